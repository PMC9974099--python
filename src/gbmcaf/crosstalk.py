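"""Directional ligand-receptor crosstalk maps between two bulk profiles.

A pair from the interaction database becomes an edge from sender to
receiver when the sender expresses the ligand at FPKM strictly greater
than 0.05 and the receiver expresses the receptor at strictly more than 10
read counts. Both thresholds are strict, so boundary values are excluded.
The ligand side is quantified in FPKM and the receptor side in read counts
— the mixed units are intentional and unit correctness is the caller's
contract. Pairs with either gene absent from its profile are dropped and
tallied, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import FormatError

__all__ = [
    "LRDatabase",
    "BulkProfile",
    "CrosstalkResult",
    "load_lr_database",
    "infer_crosstalk",
    "bidirectional_maps",
]


@dataclass
class LRDatabase:
    """Deduplicated, case-normalized ligand-receptor pair list."""

    pairs: pd.DataFrame  # columns: ligand, receptor
    source: str = ""

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        for col in ("ligand", "receptor"):
            if col not in df.columns:
                raise FormatError(f"pair database missing column {col!r}")
            df[col] = df[col].astype(str).str.strip().str.upper()
        if (df["ligand"] == "").any() or (df["receptor"] == "").any():
            raise FormatError("empty gene name in pair database")
        self.pairs = df[["ligand", "receptor"]].drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class BulkProfile:
    """One bulk sample with an FPKM layer (ligand side) and a count layer (receptor side)."""

    fpkm: pd.Series
    counts: pd.Series

    def __post_init__(self) -> None:
        self.fpkm = _upper_index(pd.Series(self.fpkm, dtype=float))
        self.counts = _upper_index(pd.Series(self.counts, dtype=float))


def _upper_index(s: pd.Series) -> pd.Series:
    s = s.copy()
    s.index = s.index.astype(str).str.upper()
    return s


@dataclass
class CrosstalkResult:
    edges: pd.DataFrame  # ligand, receptor, direction, ligand_fpkm, receptor_counts
    n_dropped: int  # database pairs with a gene absent from its profile
    direction: tuple


def load_lr_database(path, source: str | None = None) -> LRDatabase:
    """Read a ligand-receptor TSV with columns ``ligand`` and ``receptor``."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns 'ligand' and 'receptor'")
    return LRDatabase(pairs=df, source=source or str(path))


def infer_crosstalk(
    sender,
    receiver,
    db: LRDatabase,
    fpkm_min: float = 0.05,
    counts_min: float = 10,
    direction: tuple = ("sender", "receiver"),
) -> CrosstalkResult:
    """Edges for database pairs passing both strict expression thresholds.

    ``sender`` maps gene to ligand FPKM and ``receiver`` maps gene to
    receptor read counts (any mapping or Series). Pairs whose ligand or
    receptor is missing from its profile are dropped and counted.
    """
    sender = _upper_index(pd.Series(dict(sender) if not isinstance(sender, pd.Series) else sender, dtype=float))
    receiver = _upper_index(pd.Series(dict(receiver) if not isinstance(receiver, pd.Series) else receiver, dtype=float))
    if sender.empty or receiver.empty:
        raise FormatError("sender and receiver profiles must be non-empty")
    rows = []
    dropped = 0
    for lig, rec in db.pairs.itertuples(index=False):
        if lig not in sender.index or rec not in receiver.index:
            dropped += 1
            continue
        lf = float(sender[lig])
        rc = float(receiver[rec])
        if lf > fpkm_min and rc > counts_min:
            rows.append((lig, rec, f"{direction[0]}->{direction[1]}", lf, rc))
    edges = pd.DataFrame(
        rows, columns=["ligand", "receptor", "direction", "ligand_fpkm", "receptor_counts"]
    ).sort_values(["ligand", "receptor"], ignore_index=True)
    return CrosstalkResult(edges=edges, n_dropped=dropped, direction=tuple(direction))


def bidirectional_maps(
    profile_a: BulkProfile,
    profile_b: BulkProfile,
    db: LRDatabase,
    labels: tuple = ("A", "B"),
    fpkm_min: float = 0.05,
    counts_min: float = 10,
) -> tuple:
    """Apply the same thresholds in both directions (A ligands to B receptors, and back)."""
    fwd = infer_crosstalk(
        profile_a.fpkm, profile_b.counts, db,
        fpkm_min=fpkm_min, counts_min=counts_min, direction=(labels[0], labels[1]),
    )
    rev = infer_crosstalk(
        profile_b.fpkm, profile_a.counts, db,
        fpkm_min=fpkm_min, counts_min=counts_min, direction=(labels[1], labels[0]),
    )
    return fwd, rev
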