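"""Proximity curves and correlations between cell-type probability fields.

Spatial transcriptomics spots carry planar coordinates and per-spot
cell-type probabilities (already deconvolved upstream). Two questions are
answered here: how strongly two probability fields co-vary across the
tissue (Pearson correlation and its square), and how the probability of a
target type falls off with distance from the source type's territory. For
the latter, source spots are the top quantile of the source field (ties
included), every spot's distance to its nearest source spot is computed,
distances are cut into equal-width bins, and the curve reports the mean
target probability per bin. Empty bins are reported with count 0 and an
undefined mean, never interpolated. Distances are Euclidean on the supplied
coordinates, so the curve is invariant to rigid motions of the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .exceptions import FormatError, GeneLookupError, ParameterError

__all__ = [
    "SpatialMap",
    "read_spatial_map",
    "write_spatial_map",
    "rank_source_spots",
    "proximity_curve",
    "spatial_correlation",
]


@dataclass
class SpatialMap:
    """Spots with planar coordinates plus per-spot cell-type probabilities."""

    spots: pd.DataFrame  # spot_id, x, y
    prob: pd.DataFrame  # index spot_id, one column per cell type

    def __post_init__(self) -> None:
        for col in ("spot_id", "x", "y"):
            if col not in self.spots.columns:
                raise FormatError(f"spot table missing column {col!r}")
        xy = self.spots[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("spot coordinates must be finite")
        self.prob = self.prob.reindex(self.spots["spot_id"].values)
        vals = self.prob.to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            raise FormatError("every spot needs a probability for every cell type")
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise FormatError("probabilities must lie in [0, 1]")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def celltypes(self) -> list:
        return list(self.prob.columns)

    def coords(self) -> np.ndarray:
        return self.spots[["x", "y"]].to_numpy(dtype=float)

    def field(self, celltype: str) -> np.ndarray:
        if celltype not in self.prob.columns:
            raise GeneLookupError(f"unknown cell type {celltype!r}")
        return self.prob[celltype].to_numpy(dtype=float)


def read_spatial_map(path) -> SpatialMap:
    """Read a spots TSV: spot_id, x, y, then one probability column per cell type."""
    df = pd.read_csv(path, sep="\t")
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    types = [c for c in df.columns if c not in ("spot_id", "x", "y")]
    return SpatialMap(
        spots=df[["spot_id", "x", "y"]].copy(),
        prob=df.set_index("spot_id")[types],
    )


def write_spatial_map(m: SpatialMap, path) -> None:
    out = m.spots.copy()
    for ct in m.celltypes:
        out[ct] = m.prob[ct].values
    out.to_csv(path, sep="\t", index=False)


def rank_source_spots(m: SpatialMap, source_type: str, top_quantile: float = 0.1) -> np.ndarray:
    """Boolean mask of spots in the top ``top_quantile`` of the source field (ties included)."""
    if not (0.0 < top_quantile < 1.0):
        raise ParameterError("top_quantile must lie in (0, 1)")
    p = m.field(source_type)
    cutoff = np.quantile(p, 1.0 - top_quantile)
    return p >= cutoff


def proximity_curve(
    m: SpatialMap,
    source_spots: np.ndarray,
    target_type: str,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean target probability vs distance to the nearest source spot.

    Returns a frame with columns bin_mid, mean_prob (NaN on empty bins) and
    n_spots; the bins are equal-width over [0, max distance]. The
    spot-count-weighted mean of the bin means equals the global mean target
    probability.
    """
    source_spots = np.asarray(source_spots, dtype=bool)
    if not source_spots.any():
        raise ParameterError("source_spots is empty")
    if n_bins < 2:
        raise ParameterError("n_bins must be at least 2")
    target = m.field(target_type)
    xy = m.coords()
    tree = cKDTree(xy[source_spots])
    dist, _ = tree.query(xy)
    dmax = float(dist.max())
    if dmax == 0.0:
        warnings.warn("degenerate map: all spots at distance 0; single-bin output", stacklevel=2)
        return pd.DataFrame(
            {"bin_mid": [0.0], "mean_prob": [float(target.mean())], "n_spots": [m.n_spots]}
        )
    edges = np.linspace(0.0, dmax, n_bins + 1)
    # rightmost bin closed so the farthest spot is counted
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(target[sel].mean())
    return pd.DataFrame({"bin_mid": mids, "mean_prob": means, "n_spots": counts})


def spatial_correlation(m: SpatialMap, type_a: str, type_b: str) -> tuple:
    """Pearson r between two probability fields and its square."""
    a = m.field(type_a)
    b = m.field(type_b)
    if m.n_spots < 3:
        raise ParameterError("need at least 3 spots")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("correlation undefined for a constant field")
    r = float(pearsonr(a, b).statistic)
    return r, r * r
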