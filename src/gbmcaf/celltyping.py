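"""Per-cell labels, composition summaries, and CAF differentiation stage.

Labeling combines three evidence streams with a fixed precedence: the CNV
malignant flag first (malignancy is the exclusion criterion — tumor cells
with chr7+/chr10- are removed from the high-CAF-score pool), then lineage
marker detections (myeloid AIF1/PTPRC, oligodendrocyte OLIG1, endothelial
PECAM1, pericyte CSPG4/RGS5, epithelial/immune EPCAM/CD3D), and finally the
CAF probability score against a cutoff. Every cell receives exactly one
label.

Stage scoring contrasts an early signature (EVA1B, DDIT4) with a late,
fully differentiated signature (ACTA2, SRGN): the stage ratio is the
late-minus-early mean log expression, and the population summary reports
the fraction of CAFs that are late-dominant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GbmCafError, PanelError
from .io_qc import CountMatrix, NormalizedMatrix
from .scoring import ScoreResult

__all__ = [
    "DEFAULT_LINEAGE_MARKERS",
    "CellTypeCalls",
    "Composition",
    "StageScores",
    "assign_labels",
    "composition_summary",
    "stage_scores",
]

# precedence order after the malignant flag; dict order is the rule order
DEFAULT_LINEAGE_MARKERS = {
    "myeloid": ("AIF1", "PTPRC"),
    "oligodendrocyte": ("OLIG1",),
    "endothelial": ("PECAM1",),
    "pericyte": ("CSPG4", "RGS5"),
    "epithelial_immune": ("EPCAM", "CD3D"),
}

LABELS = (
    "CAF",
    "malignant",
    "myeloid",
    "oligodendrocyte",
    "endothelial",
    "pericyte",
    "epithelial_immune",
    "unassigned",
)


@dataclass
class CellTypeCalls:
    """One label per cell plus the evidence each rule saw."""

    labels: pd.Series
    evidence: pd.DataFrame  # p, malignant, per-rule detection flags
    cutoff: float


@dataclass
class Composition:
    fractions: dict
    n_cells: int
    assigned_fractions: dict


@dataclass
class StageScores:
    early: pd.Series
    late: pd.Series
    stage_ratio: pd.Series  # late - early, log scale
    fraction_late_dominant: float


def assign_labels(
    m: CountMatrix,
    scores: ScoreResult,
    malignant: np.ndarray,
    lineage_markers: dict | None = None,
    cutoff: float = 0.6,
    detect_min: int = 1,
) -> CellTypeCalls:
    """Deterministic precedence labeling; see the module docstring for the order.

    ``malignant`` is the per-cell CNV flag aligned with ``m``; lineage rules
    whose genes are all absent are skipped with a warning.
    """
    if lineage_markers is None:
        lineage_markers = DEFAULT_LINEAGE_MARKERS
    n = m.n_cells
    malignant = np.asarray(malignant, dtype=bool)
    if malignant.shape != (n,):
        raise GbmCafError("malignant flag not aligned with the matrix cells")
    p = scores.p.reindex(m.cell_ids).to_numpy()
    if np.any(np.isnan(p)):
        raise GbmCafError("scores not aligned with the matrix cells")

    detections = {}
    for label, genes in lineage_markers.items():
        present = [g for g in genes if m.has_gene(g)]
        missing = [g for g in genes if not m.has_gene(g)]
        if missing:
            warnings.warn(
                f"lineage rule {label!r}: missing marker(s) {missing} skipped", stacklevel=2
            )
        hit = np.zeros(n, dtype=bool)
        for g in present:
            hit |= m.gene_counts(g) >= detect_min
        detections[label] = hit if present else None

    labels = np.full(n, "unassigned", dtype=object)
    unset = np.ones(n, dtype=bool)

    labels[malignant] = "malignant"
    unset &= ~malignant
    for label, hit in detections.items():
        if hit is None:
            continue
        take = unset & hit
        labels[take] = label
        unset &= ~take
    caf = unset & (p >= cutoff)
    labels[caf] = "CAF"

    evidence = pd.DataFrame({"p": p, "malignant": malignant}, index=m.cell_ids)
    for label, hit in detections.items():
        evidence[f"detected_{label}"] = hit if hit is not None else False
    return CellTypeCalls(
        labels=pd.Series(labels, index=m.cell_ids, name="label"),
        evidence=evidence,
        cutoff=cutoff,
    )


def composition_summary(calls: CellTypeCalls) -> Composition:
    """Label fractions over all cells, plus fractions over assigned cells only."""
    labels = calls.labels
    if len(labels) == 0:
        raise GbmCafError("no cells to summarize")
    counts = labels.value_counts()
    n = len(labels)
    fractions = {lab: counts.get(lab, 0) / n for lab in counts.index}
    assigned = labels[labels != "unassigned"]
    if len(assigned):
        ac = assigned.value_counts()
        assigned_fractions = {lab: ac[lab] / len(assigned) for lab in ac.index}
    else:
        assigned_fractions = {}
    return Composition(fractions=fractions, n_cells=n, assigned_fractions=assigned_fractions)


def stage_scores(
    norm: NormalizedMatrix,
    caf_mask=None,
    early_genes=("EVA1B", "DDIT4"),
    late_genes=("ACTA2", "SRGN"),
) -> StageScores:
    """Early vs late CAF signature contrast on the log scale.

    ``caf_mask`` restricts the summary statistic (fraction late-dominant) to
    the CAF population; the per-cell scores cover every cell.
    """
    early_present = [g for g in early_genes if norm.has_gene(g)]
    late_present = [g for g in late_genes if norm.has_gene(g)]
    if not early_present or not late_present:
        raise PanelError("both the early and late gene sets must have a present gene")
    early = norm.dense(early_present).mean(axis=1)
    late = norm.dense(late_present).mean(axis=1)
    ratio = late - early
    if caf_mask is None:
        mask = np.ones(norm.n_cells, dtype=bool)
    else:
        mask = np.asarray(caf_mask, dtype=bool)
    frac = float((ratio[mask] > 0).mean()) if mask.any() else float("nan")
    idx = norm.cell_ids
    return StageScores(
        early=pd.Series(early, index=idx, name="early"),
        late=pd.Series(late, index=idx, name="late"),
        stage_ratio=pd.Series(ratio, index=idx, name="stage_ratio"),
        fraction_late_dominant=frac,
    )
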