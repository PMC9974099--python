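"""Synthetic ground-truth data for every pipeline stage.

The generator emulates the data regime the pipeline is built for:

* droplet scRNA-seq counts over a compact gene universe (2,000 autosomal
  genes plus the 13 ``MT-`` mitochondrial genes), negative-binomial per gene
  with cell-specific library size drawn lognormal and a Beta-distributed
  mitochondrial fraction;
* planted cell populations (CAF, myeloid, malignant, oligodendrocyte, plus
  optional endothelial/pericyte/epithelial-immune/astrocyte contaminants)
  whose lineage marker genes are expressed at ``marker_fold_change`` times
  the baseline rate in the owning population and are silent elsewhere.
  Lineage exclusivity is deliberate: canonical markers such as AIF1 or
  EPCAM are effectively absent outside their lineage in real data, and the
  detection-based negative-selection strategy the pipeline implements is
  meaningful only under that regime;
* the glioblastoma hallmark genotype in malignant cells: chromosome 7 gene
  rates multiplied by ``cnv_gain_fold`` and chromosome 10 rates by
  ``cnv_loss_fold``;
* bulk ligand (FPKM) / receptor (read-count) profiles with genes planted
  strictly above, strictly below, or exactly at the crosstalk thresholds;
* 2-D spot grids whose per-cell-type probability fields are mixtures of
  planar Gaussian bumps, with colocalized type pairs sharing bump centers.

All outputs are bit-for-bit reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .crosstalk import BulkProfile, LRDatabase
from .exceptions import ConfigurationError
from .io_qc import CountMatrix
from .spatial import SpatialMap

__all__ = [
    "SimulationConfig",
    "LabeledCounts",
    "BulkSim",
    "CrosstalkScenario",
    "DEFAULT_POPULATION_FRACTIONS",
    "DEFAULT_MARKER_ASSIGNMENTS",
    "gene_universe",
    "simulate_counts",
    "simulate_bulk_profiles",
    "simulate_crosstalk_scenario",
    "simulate_spatial_map",
]

# GRCh38 autosome lengths in Mb, used to spread the gene universe.
_CHROM_MB = {
    "1": 248.96, "2": 242.19, "3": 198.30, "4": 190.21, "5": 181.54,
    "6": 170.81, "7": 159.35, "8": 145.14, "9": 138.39, "10": 133.80,
    "11": 135.09, "12": 133.28, "13": 114.36, "14": 107.04, "15": 101.99,
    "16": 90.34, "17": 83.26, "18": 80.37, "19": 58.62, "20": 64.44,
    "21": 46.71, "22": 50.82,
}

_MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

DEFAULT_POPULATION_FRACTIONS = {
    "CAF": 0.52,
    "myeloid": 0.22,
    "malignant": 0.20,
    "oligodendrocyte": 0.06,
}

# Markers belong to exactly one population; populations absent from the
# fraction map contribute no cells, so their markers stay silent, which keeps
# the negative-selection and lineage-precedence genes clean in a default run.
DEFAULT_MARKER_ASSIGNMENTS = {
    "CAF": ["ACTA2", "FAP", "PDGFRA", "PDGFRB", "PDPN", "S100A4", "TNC", "VIM", "COL1A1"],
    "myeloid": ["AIF1", "PTPRC"],
    "malignant": [],
    "oligodendrocyte": ["OLIG1"],
    "endothelial": ["PECAM1", "CD34"],
    "pericyte": ["CSPG4", "RGS5"],
    "epithelial_immune": ["EPCAM", "CD3D"],
    "astrocyte": ["GFAP", "AQP4", "SLC1A3", "SLC1A2", "S100B",
                  "ALDH1L1", "GJA1", "SOX9", "NDRG2", "FGFR3"],
}

# Regular (non-marker) genes that downstream stages address by name.
_EXTRA_NAMED_GENES = ("EVA1B", "DDIT4", "SRGN")

# Chromosomes that never host named marker genes, so the planted CNV signal
# and the planted marker signal stay separable.
_CNV_CHROMS = ("7", "10")


@dataclass
class SimulationConfig:
    """Parameters of the planted-population count simulator.

    ``baseline_mean`` and ``marker_fold_change`` are relative expression
    rates; each cell's per-gene means are rescaled so its expected non-
    mitochondrial total equals the drawn depth times (1 - mito fraction).
    """

    n_cells: int = 5000
    population_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_FRACTIONS)
    )
    n_genes: int = 2000
    marker_assignments: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_ASSIGNMENTS.items()}
    )
    marker_fold_change: float = 8.0
    baseline_mean: float = 0.2
    nb_dispersion: float = 0.5
    depth_lognormal_mu_sigma: tuple = (math.log(5000.0), 0.35)
    mito_fraction_beta_params: tuple = (2.0, 38.0)
    cnv_gain_fold: float = 1.5
    cnv_loss_fold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells and n_genes must be positive")
        fracs = np.array(list(self.population_fractions.values()), dtype=float)
        if len(fracs) == 0:
            raise ConfigurationError("population_fractions is empty")
        if np.any(fracs < 0):
            raise ConfigurationError("population fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"population fractions sum to {fracs.sum():.12g}, expected 1"
            )
        seen: dict[str, str] = {}
        for pop, genes in self.marker_assignments.items():
            for g in genes:
                if g in seen:
                    raise ConfigurationError(
                        f"marker gene {g!r} assigned to both {seen[g]!r} and {pop!r}"
                    )
                seen[g] = pop
        for p, name in [
            (self.marker_fold_change, "marker_fold_change"),
            (self.baseline_mean, "baseline_mean"),
            (self.nb_dispersion, "nb_dispersion"),
            (self.cnv_gain_fold, "cnv_gain_fold"),
        ]:
            if p <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not (0 < self.cnv_loss_fold < 1):
            raise ConfigurationError("cnv_loss_fold must lie in (0, 1)")
        a, b = self.mito_fraction_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError("mito Beta parameters must be positive")
        named = set(seen) | set(_EXTRA_NAMED_GENES)
        if len(named) >= self.n_genes // 2:
            raise ConfigurationError("n_genes too small to host the named marker genes")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class LabeledCounts:
    """Counts plus the planted truth: one label per cell, one annotation per gene."""

    counts: CountMatrix
    truth_labels: pd.Series
    gene_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.truth_labels) != self.counts.n_cells:
            raise ConfigurationError("one truth label per cell required")
        if len(self.gene_annotation) != self.counts.n_genes:
            raise ConfigurationError("one annotation row per gene required")


def gene_universe(n_genes: int = 2000, named_genes: Sequence[str] = ()) -> pd.DataFrame:
    """Deterministic gene annotation: ``n_genes`` autosomal genes plus 13 MT- genes.

    Genes are spread over the 22 autosomes proportionally to chromosome
    length and evenly spaced within each chromosome. Named genes replace
    evenly spaced placeholder slots on autosomes other than 7 and 10, so
    marker programs never confound the planted CNV.
    """
    total = sum(_CHROM_MB.values())
    raw = {c: n_genes * l / total for c, l in _CHROM_MB.items()}
    alloc = {c: int(math.floor(v)) for c, v in raw.items()}
    # largest-remainder rounding to hit n_genes exactly
    remainder = sorted(raw, key=lambda c: raw[c] - alloc[c], reverse=True)
    short = n_genes - sum(alloc.values())
    for c in remainder[:short]:
        alloc[c] += 1

    rows = []
    i = 0
    for c in _CHROM_MB:
        n_c = alloc[c]
        if n_c == 0:
            continue
        spacing = _CHROM_MB[c] * 1e6 / n_c
        for k in range(n_c):
            rows.append((f"GENE{i + 1:05d}", c, int((k + 0.5) * spacing)))
            i += 1
    ann = pd.DataFrame(rows, columns=["gene", "chromosome", "start"])

    named = list(dict.fromkeys(named_genes))  # preserve order, dedupe
    if named:
        host = np.flatnonzero(~ann["chromosome"].isin(_CNV_CHROMS))
        if len(named) > len(host):
            raise ConfigurationError("too many named genes for the gene universe")
        slots = host[np.linspace(0, len(host) - 1, len(named)).astype(int)]
        genes = ann["gene"].to_numpy(dtype=object)
        genes[slots] = named
        ann["gene"] = genes

    mt = pd.DataFrame(
        {
            "gene": list(_MITO_GENES),
            "chromosome": "MT",
            "start": [1000 * k for k in range(len(_MITO_GENES))],
        }
    )
    return pd.concat([ann, mt], ignore_index=True)


def simulate_counts(config: SimulationConfig) -> LabeledCounts:
    """Draw a planted-population count matrix under ``config``.

    Population labels are iid draws at the configured fractions. A cell's
    expected count for gene g is proportional to the population's relative
    rate for g (baseline, marker fold, and CNV folds applied) and rescaled so
    the expected non-mitochondrial total equals depth x (1 - mito fraction);
    the 13 MT- genes share the mito fraction of the depth. Counts are
    negative binomial with variance mu + dispersion * mu^2.
    """
    config.validate()
    named = []
    for genes in config.marker_assignments.values():
        named.extend(genes)
    named.extend(_EXTRA_NAMED_GENES)
    ann = gene_universe(config.n_genes, named)

    genes = ann["gene"].to_numpy(dtype=object)
    chrom = ann["chromosome"].to_numpy(dtype=object)
    is_mito = chrom == "MT"
    n_mito = int(is_mito.sum())
    auto_idx = np.flatnonzero(~is_mito)
    gene_pos = {g: i for i, g in enumerate(genes)}

    marker_owner: dict[str, str] = {}
    for pop, mg in config.marker_assignments.items():
        for g in mg:
            if g not in gene_pos:
                raise ConfigurationError(f"marker gene {g!r} not in gene universe")
            marker_owner[g] = pop

    pops = list(config.population_fractions.keys())
    fracs = np.array([config.population_fractions[p] for p in pops], dtype=float)

    # Relative rate vectors per population over autosomal genes.
    base = np.full(len(genes), config.baseline_mean, dtype=float)
    for g in marker_owner:
        base[gene_pos[g]] = 0.0  # markers are silent outside their population
    weights = {}
    for pop in pops:
        w = base.copy()
        for g in config.marker_assignments.get(pop, []):
            w[gene_pos[g]] = config.baseline_mean * config.marker_fold_change
        if pop == "malignant":
            w[chrom == "7"] *= config.cnv_gain_fold
            w[chrom == "10"] *= config.cnv_loss_fold
        weights[pop] = w[auto_idx]

    rng = np.random.default_rng(config.seed)
    label_idx = rng.choice(len(pops), size=config.n_cells, p=fracs)
    mu_ln, sigma_ln = config.depth_lognormal_mu_sigma
    depth = rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=config.n_cells)
    a, b = config.mito_fraction_beta_params
    mito_frac = rng.beta(a, b, size=config.n_cells)

    w_matrix = np.stack([weights[pops[i]] for i in range(len(pops))])
    w_cells = w_matrix[label_idx]  # cells x autosomal genes
    row_sum = w_cells.sum(axis=1)
    mu_auto = w_cells * (depth * (1.0 - mito_frac) / row_sum)[:, None]
    mu_mito = np.repeat((depth * mito_frac / n_mito)[:, None], n_mito, axis=1)

    mu = np.empty((config.n_cells, len(genes)), dtype=float)
    mu[:, auto_idx] = mu_auto
    mu[:, np.flatnonzero(is_mito)] = mu_mito

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cells = np.array([f"CELL{i + 1:05d}" for i in range(config.n_cells)], dtype=object)
    labels = pd.Series([pops[i] for i in label_idx], index=cells, name="label")
    cm = CountMatrix(cells, genes, sp.csr_matrix(counts))
    return LabeledCounts(counts=cm, truth_labels=labels, gene_annotation=ann)


@dataclass
class BulkSim:
    """One planted bulk profile pair plus the plant list as truth."""

    ligand_fpkm: pd.Series
    receptor_counts: pd.Series
    truth: pd.DataFrame  # columns: gene, role, relation, value


def simulate_bulk_profiles(
    n_ligands_above: int = 10,
    n_ligands_below: int = 9,
    n_ligands_at: int = 1,
    n_receptors_above: int = 10,
    n_receptors_below: int = 9,
    n_receptors_at: int = 1,
    fpkm_min: float = 0.05,
    counts_min: int = 10,
    seed: int = 0,
) -> BulkSim:
    """Plant ligand FPKMs and receptor read counts around the crosstalk thresholds.

    Genes in the ``above`` groups are strictly above the threshold, ``below``
    strictly below, and ``at`` exactly at it (hence excluded by the strict
    filter). The truth table records every plant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fpkm = {}
    counts = {}
    i = 0
    for relation, n in (("above", n_ligands_above), ("below", n_ligands_below), ("at", n_ligands_at)):
        for _ in range(n):
            i += 1
            g = f"L{i:03d}"
            if relation == "above":
                v = fpkm_min * rng.uniform(1.5, 40.0)
            elif relation == "below":
                v = fpkm_min * rng.uniform(0.0, 0.8)
            else:
                v = fpkm_min
            fpkm[g] = float(v)
            rows.append((g, "ligand", relation, float(v)))
    j = 0
    for relation, n in (
        ("above", n_receptors_above),
        ("below", n_receptors_below),
        ("at", n_receptors_at),
    ):
        for _ in range(n):
            j += 1
            g = f"R{j:03d}"
            if relation == "above":
                v = int(rng.integers(counts_min + 1, counts_min * 20))
            elif relation == "below":
                v = int(rng.integers(0, counts_min))
            else:
                v = counts_min
            counts[g] = v
            rows.append((g, "receptor", relation, float(v)))
    truth = pd.DataFrame(rows, columns=["gene", "role", "relation", "value"])
    return BulkSim(
        ligand_fpkm=pd.Series(fpkm, name="fpkm"),
        receptor_counts=pd.Series(counts, name="counts", dtype=float),
        truth=truth,
    )


@dataclass
class CrosstalkScenario:
    """Two bulk profiles, a pair database, and the planted directional truth."""

    profile_a: BulkProfile
    profile_b: BulkProfile
    database: LRDatabase
    truth: pd.DataFrame  # columns: ligand, receptor, planted (forward/reverse/none)


def simulate_crosstalk_scenario(
    n_forward: int = 10,
    n_reverse: int = 7,
    n_silent: int = 8,
    fpkm_min: float = 0.05,
    counts_min: int = 10,
    seed: int = 0,
) -> CrosstalkScenario:
    """Plant a bidirectional crosstalk ground truth between profiles A and B.

    ``forward`` pairs pass the thresholds only A->B, ``reverse`` only B->A,
    and ``silent`` pairs fail at least one side in both directions.
    """
    rng = np.random.default_rng(seed)
    n = n_forward + n_reverse + n_silent
    ligands = [f"LIG{i + 1:03d}" for i in range(n)]
    receptors = [f"REC{i + 1:03d}" for i in range(n)]
    kinds = ["forward"] * n_forward + ["reverse"] * n_reverse + ["none"] * n_silent

    def hi_fpkm():
        return float(fpkm_min * rng.uniform(1.5, 40.0))

    def lo_fpkm():
        return float(fpkm_min * rng.uniform(0.0, 0.8))

    def hi_counts():
        return float(rng.integers(counts_min + 1, counts_min * 20))

    def lo_counts():
        return float(rng.integers(0, counts_min))

    a_fpkm, a_counts, b_fpkm, b_counts = {}, {}, {}, {}
    rows = []
    for lig, rec, kind in zip(ligands, receptors, kinds):
        if kind == "forward":
            a_fpkm[lig], b_counts[rec] = hi_fpkm(), hi_counts()
            b_fpkm[lig], a_counts[rec] = lo_fpkm(), lo_counts()
        elif kind == "reverse":
            a_fpkm[lig], b_counts[rec] = lo_fpkm(), lo_counts()
            b_fpkm[lig], a_counts[rec] = hi_fpkm(), hi_counts()
        else:
            # fail the ligand side in one direction and the receptor side in the other
            a_fpkm[lig], b_counts[rec] = lo_fpkm(), hi_counts()
            b_fpkm[lig], a_counts[rec] = hi_fpkm(), lo_counts()
        rows.append((lig, rec, kind))

    profile_a = BulkProfile(fpkm=pd.Series(a_fpkm), counts=pd.Series(a_counts))
    profile_b = BulkProfile(fpkm=pd.Series(b_fpkm), counts=pd.Series(b_counts))
    db = LRDatabase(
        pairs=pd.DataFrame({"ligand": ligands, "receptor": receptors}),
        source="synthetic plant",
    )
    truth = pd.DataFrame(rows, columns=["ligand", "receptor", "planted"])
    return CrosstalkScenario(profile_a=profile_a, profile_b=profile_b, database=db, truth=truth)


def simulate_spatial_map(
    n_spots_side: int,
    celltypes: Sequence[str],
    colocalized_pairs: Sequence[tuple] = (),
    seed: int = 0,
    n_bumps: int = 2,
) -> SpatialMap:
    """Regular grid with Gaussian-bump probability fields per cell type.

    Each type's field is a mixture of ``n_bumps`` planar Gaussian bumps,
    max-normalized into [0, 1]. Colocalized pairs share bump centers (bump
    widths stay type-specific, so shared-center fields are strongly but not
    perfectly correlated); all other types draw independent centers.
    """
    if n_spots_side < 4:
        raise ConfigurationError("n_spots_side must be at least 4")
    celltypes = list(celltypes)
    known = set(celltypes)
    for a, b in colocalized_pairs:
        if a not in known or b not in known:
            raise ConfigurationError(f"colocalized pair ({a!r}, {b!r}) uses unknown cell type")

    rng = np.random.default_rng(seed)
    side = n_spots_side
    xx, yy = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    xs, ys = xx.ravel(), yy.ravel()

    centers = {}
    sigmas = {}
    for ct in celltypes:
        centers[ct] = rng.uniform(0, side - 1, size=(n_bumps, 2))
        sigmas[ct] = rng.uniform(side / 8.0, side / 4.0, size=n_bumps)
    for a, b in colocalized_pairs:
        centers[b] = centers[a]

    prob = {}
    for ct in celltypes:
        f = np.zeros(side * side)
        for (cx, cy), s in zip(centers[ct], sigmas[ct]):
            f += np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * s * s))
        prob[ct] = f / f.max()

    spots = pd.DataFrame(
        {
            "spot_id": [f"SPOT{i + 1:05d}" for i in range(side * side)],
            "x": xs,
            "y": ys,
        }
    )
    return SpatialMap(spots=spots, prob=pd.DataFrame(prob, index=spots["spot_id"].values))
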