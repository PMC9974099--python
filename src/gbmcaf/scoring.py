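"""Kernel-based marker-panel probability scores and negative selection.

The CAF probability score of a cell combines the *degree of expression* of
nine positive CAF markers with the *absence* of five markers of non-CAF
stromal cells that share surface markers with fibroblasts. With u the
log-normalized expression of a panel gene and k a Gaussian kernel

    k(u) = exp(-u^2 / (2 h^2)),

the score is the mean over the n panel genes present in the matrix of
(1 - k(u)) for positive markers and k(u) for negative markers:

    p = (1/n) [ sum_{g in positives} (1 - k(u_g)) + sum_{g in negatives} k(u_g) ]

so a cell scores 1 when every positive marker is strongly expressed and
every negative marker is silent. Each term lies in [0, 1], hence p does too.
Panel genes missing from the matrix are dropped from both the sum and n and
reported; nothing is imputed.

The same machinery scores astrocytes with a 10-marker all-positive panel,
and a detection-based negative selection excludes cells expressing
epithelial (EPCAM), endothelial (PECAM1), pericyte (CSPG4) or immune
(PTPRC) surface markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeneLookupError, PanelError, ParameterError
from .io_qc import CountMatrix, NormalizedMatrix

__all__ = [
    "MarkerPanel",
    "ScoreResult",
    "CutoffResult",
    "NegativeSelectionResult",
    "CAF_PANEL",
    "ASTROCYTE_PANEL",
    "DEFAULT_EXCLUSION_GENES",
    "gaussian_kernel",
    "panel_probability",
    "astrocyte_probability",
    "negative_selection",
    "marker_prevalence",
    "panel_coverage",
    "high_score_cutoff",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Named positive/negative marker gene sets.

    Positives must be non-empty; negatives may be empty (all-positive panels
    such as the astrocyte score), and the two sides must be disjoint.
    """

    name: str
    positives: tuple = ()
    negatives: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(self.positives))
        object.__setattr__(self, "negatives", tuple(self.negatives))
        if not self.positives:
            raise PanelError(f"panel {self.name!r} has no positive markers")
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise PanelError(f"panel {self.name!r} genes on both sides: {sorted(overlap)}")

    @property
    def size(self) -> int:
        return len(self.positives) + len(self.negatives)


CAF_PANEL = MarkerPanel(
    name="CAF",
    positives=("ACTA2", "FAP", "PDGFRA", "PDGFRB", "PDPN", "S100A4", "TNC", "VIM", "COL1A1"),
    negatives=("PTPRC", "EPCAM", "PECAM1", "CSPG4", "RGS5"),
)

# Stand-in 10-marker astrocyte panel of canonical astrocyte genes; the
# original study's exact list lives in supplementary material.
ASTROCYTE_PANEL = MarkerPanel(
    name="astrocyte",
    positives=("GFAP", "AQP4", "SLC1A3", "SLC1A2", "S100B",
               "ALDH1L1", "GJA1", "SOX9", "NDRG2", "FGFR3"),
)

DEFAULT_EXCLUSION_GENES = ("EPCAM", "PECAM1", "CSPG4", "PTPRC")


@dataclass
class ScoreResult:
    """Per-cell panel probabilities plus the score's bookkeeping."""

    p: pd.Series
    n: int
    bandwidth: float
    missing_genes: list = field(default_factory=list)
    panel_name: str = ""


@dataclass
class CutoffResult:
    cutoff: float
    mask: np.ndarray
    method: str


@dataclass
class NegativeSelectionResult:
    retained: np.ndarray  # boolean, True = cell kept
    exclusion_tally: pd.Series  # cells excluded per exclusion gene
    missing_genes: list


def gaussian_kernel(u, h: float = 1.0):
    """Gaussian kernel k(u) = exp(-u^2 / (2 h^2)); k(0) = 1, decreasing in |u|."""
    if h <= 0:
        raise ParameterError("bandwidth h must be strictly positive")
    u = np.asarray(u, dtype=float)
    out = np.exp(-(u * u) / (2.0 * h * h))
    return float(out) if out.ndim == 0 else out


def panel_probability(
    norm: NormalizedMatrix, panel: MarkerPanel, h: float = 1.0
) -> ScoreResult:
    """Per-cell panel probability p in [0, 1]; see the module docstring for the form."""
    pos = [g for g in panel.positives if norm.has_gene(g)]
    neg = [g for g in panel.negatives if norm.has_gene(g)]
    missing = [g for g in panel.positives + panel.negatives if not norm.has_gene(g)]
    n = len(pos) + len(neg)
    if n == 0:
        raise PanelError(f"no gene of panel {panel.name!r} present in the matrix")
    if missing:
        warnings.warn(
            f"panel {panel.name!r}: {len(missing)} gene(s) absent and dropped: {missing}",
            stacklevel=2,
        )
    total = np.zeros(norm.n_cells)
    if pos:
        k = gaussian_kernel(norm.dense(pos), h)
        total += (1.0 - k).sum(axis=1)
    if neg:
        k = gaussian_kernel(norm.dense(neg), h)
        total += k.sum(axis=1)
    p = np.clip(total / n, 0.0, 1.0)
    return ScoreResult(
        p=pd.Series(p, index=norm.cell_ids, name="p"),
        n=n,
        bandwidth=h,
        missing_genes=missing,
        panel_name=panel.name,
    )


def astrocyte_probability(
    norm: NormalizedMatrix, astro_panel: MarkerPanel = ASTROCYTE_PANEL, h: float = 1.0
) -> ScoreResult:
    """Astrocyte probability: an all-positive panel (the negative sum is 0)."""
    return panel_probability(norm, astro_panel, h=h)


def negative_selection(
    m: CountMatrix,
    exclusion_genes=DEFAULT_EXCLUSION_GENES,
    detect_min: int = 1,
) -> NegativeSelectionResult:
    """Exclude cells detecting any exclusion marker at >= ``detect_min`` counts.

    Markers absent from the matrix are skipped with a warning. The tally
    counts excluded cells per gene (a cell can appear under several genes).
    """
    present = [g for g in exclusion_genes if m.has_gene(g)]
    missing = [g for g in exclusion_genes if not m.has_gene(g)]
    if missing:
        warnings.warn(f"exclusion genes absent and skipped: {missing}", stacklevel=2)
    excluded = np.zeros(m.n_cells, dtype=bool)
    tally = {}
    for g in present:
        hit = m.gene_counts(g) >= detect_min
        tally[g] = int(hit.sum())
        excluded |= hit
    return NegativeSelectionResult(
        retained=~excluded,
        exclusion_tally=pd.Series(tally, dtype=int),
        missing_genes=missing,
    )


def _resolve_mask(n: int, within) -> np.ndarray:
    if within is None:
        return np.ones(n, dtype=bool)
    within = np.asarray(within, dtype=bool)
    if within.shape != (n,):
        raise ParameterError("mask length does not match cell count")
    return within


def marker_prevalence(
    m: CountMatrix, gene: str, detect_min: int = 1, within=None
) -> float:
    """Fraction of masked cells with count(gene) >= detect_min."""
    if not m.has_gene(gene):
        raise GeneLookupError(f"gene {gene!r} not in matrix")
    mask = _resolve_mask(m.n_cells, within)
    if mask.sum() == 0:
        return float("nan")
    return float((m.gene_counts(gene)[mask] >= detect_min).mean())


def panel_coverage(
    m: CountMatrix, panel_positives, detect_min: int = 1, within=None
) -> float:
    """Fraction of masked cells detecting at least one panel gene."""
    present = [g for g in panel_positives if m.has_gene(g)]
    if not present:
        raise PanelError("no panel gene present in the matrix")
    mask = _resolve_mask(m.n_cells, within)
    if mask.sum() == 0:
        return float("nan")
    any_hit = np.zeros(m.n_cells, dtype=bool)
    for g in present:
        any_hit |= m.gene_counts(g) >= detect_min
    return float(any_hit[mask].mean())


def high_score_cutoff(
    scores: ScoreResult, method: str = "fixed", value: float = 0.6
) -> CutoffResult:
    """Turn scores into a flagged-cell mask; ties break toward flagging (>=)."""
    p = scores.p.to_numpy()
    if p.size == 0:
        raise ParameterError("empty score vector")
    if method == "fixed":
        cutoff = float(value)
    elif method == "quantile":
        if not (0.0 < value < 1.0):
            raise ParameterError("quantile value must lie in (0, 1)")
        cutoff = float(np.quantile(p, value))
    else:
        raise ParameterError(f"unknown cutoff method {method!r}")
    return CutoffResult(cutoff=cutoff, mask=p >= cutoff, method=method)
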