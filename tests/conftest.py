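"""Shared fixtures: tiny hand-built matrices and one full default synthetic run."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gbmcaf import (
    CAF_PANEL,
    CountMatrix,
    NormalizedMatrix,
    SimulationConfig,
    bin_genes,
    call_chromosome_events,
    compute_cell_qc,
    infer_cnv,
    is_gbm_malignant,
    log_normalize,
    panel_probability,
    qc_filter,
    simulate_counts,
)


def make_counts(gene_to_counts: dict, cells=None) -> CountMatrix:
    """Build a CountMatrix from {gene: per-cell count list}."""
    genes = list(gene_to_counts)
    mat = np.array([gene_to_counts[g] for g in genes]).T
    if cells is None:
        cells = [f"c{i}" for i in range(mat.shape[0])]
    return CountMatrix(np.array(cells, dtype=object), np.array(genes, dtype=object), sp.csr_matrix(mat))


def make_norm(gene_to_values: dict, cells=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from {gene: per-cell value list}."""
    genes = list(gene_to_values)
    mat = np.array([gene_to_values[g] for g in genes], dtype=float).T
    if cells is None:
        cells = [f"c{i}" for i in range(mat.shape[0])]
    return NormalizedMatrix(np.array(cells, dtype=object), np.array(genes, dtype=object), sp.csr_matrix(mat))


@dataclass
class DefaultRun:
    """The default synthetic study condition carried through the whole pipeline."""

    labeled: object
    matrix: object  # QC-filtered counts
    truth: pd.Series  # truth labels aligned to the filtered cells
    norm: object
    scores: object
    malignant: np.ndarray  # two-pass, reference-free calls
    malignant_refnormal: np.ndarray  # calls referenced to planted normal cells
    profile_refnormal: object


@pytest.fixture(scope="session")
def default_run() -> DefaultRun:
    """Simulate 5,000 cells at the default fractions (seed 1) and run every stage."""
    labeled = simulate_counts(SimulationConfig(seed=1))
    res = qc_filter(labeled.counts, compute_cell_qc(labeled.counts))
    m = res.matrix
    truth = labeled.truth_labels.reindex(m.cell_ids)
    norm = log_normalize(m)
    scores = panel_probability(norm, CAF_PANEL)

    autosomal = labeled.gene_annotation[labeled.gene_annotation["chromosome"] != "MT"]
    bins = bin_genes(autosomal)

    profile = infer_cnv(norm, bins)
    malignant = is_gbm_malignant(call_chromosome_events(profile))
    if 0 < malignant.sum() < m.n_cells:
        profile = infer_cnv(norm, bins, reference=~malignant)
        malignant = is_gbm_malignant(call_chromosome_events(profile))

    normal_mask = (truth != "malignant").to_numpy()
    profile_ref = infer_cnv(norm, bins, reference=normal_mask)
    malignant_ref = is_gbm_malignant(call_chromosome_events(profile_ref))

    return DefaultRun(
        labeled=labeled,
        matrix=m,
        truth=truth,
        norm=norm,
        scores=scores,
        malignant=malignant,
        malignant_refnormal=malignant_ref,
        profile_refnormal=profile_ref,
    )
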