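"""Expression normalization and rank/level binning.

Raw abundance tables (clone counts for miRNA precursors, FPKM-like values
for genes) are normalized — the larger of the 3p/5p arm counts per
precursor, brain sub-regions averaged — and then binned per organ:

* miRNA precursors into five ranks, rank 1 = "mute" (zero in this organ,
  detectable in at least one other), ranks 2-5 equally populated in
  increasing order of expression;
* genes into eleven levels (I-XI) with the same convention.

A cross-organ variant bins every (gene, organ) value on one global scale,
which is what the repression level-shift analysis compares across organs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FIVE_RANK = "five_rank"
ELEVEN_LEVEL = "eleven_level"


class BinningError(ValueError):
    pass


@dataclass
class RankTable:
    """Integer ranks/levels per entity per organ; rank 1 marks mute entries."""

    ranks: pd.DataFrame  # entities x organs, int
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (FIVE_RANK, ELEVEN_LEVEL):
            raise BinningError(f"unknown scale {self.scale!r}")

    @property
    def n_bins(self) -> int:
        return 5 if self.scale == FIVE_RANK else 11

    @property
    def mute_mask(self) -> pd.DataFrame:
        return self.ranks.eq(1)

    def column(self, organ: str) -> pd.Series:
        return self.ranks[organ]


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.columns.duplicated().any():
        raise BinningError("organ names must be unique")
    if (expr.values < 0).any():
        raise BinningError("expression values must be nonnegative")


def collapse_arm_counts(
    arm_counts: pd.DataFrame, precursor_col: str = "precursor_id"
) -> pd.DataFrame:
    """Collapse 3p/5p arm abundances to one value per precursor per organ.

    ``arm_counts`` holds one row per sequenced arm with a ``precursor_id``
    column (and optionally an ``arm`` column, ignored); every remaining
    column is an organ. Where both arms were measured the larger count is
    used; a single measured arm stands as-is.
    """
    if precursor_col not in arm_counts.columns:
        raise BinningError(f"missing column {precursor_col!r}")
    organ_cols = [
        c for c in arm_counts.columns if c not in (precursor_col, "arm")
    ]
    values = arm_counts[organ_cols]
    if (values.values < 0).any():
        raise BinningError("negative counts")
    sizes = arm_counts.groupby(precursor_col).size()
    if (sizes > 2).any():
        raise BinningError("a precursor may contribute at most two arms")
    collapsed = arm_counts.groupby(precursor_col)[organ_cols].max()
    collapsed.index.name = "precursor_id"
    return collapsed


def aggregate_brain_subregions(
    expr: pd.DataFrame,
    subregions: Sequence[str],
    name: str = "brain",
) -> pd.DataFrame:
    """Replace named sub-region columns by their arithmetic mean.

    Only sub-regions present in the table enter the mean; at least one must
    be present. The merged column is inserted where the first sub-region
    stood, other columns keep their order.
    """
    present = [s for s in subregions if s in expr.columns]
    if not present:
        raise BinningError(
            f"none of the sub-regions {list(subregions)} present in the table"
        )
    mean = expr[present].mean(axis=1)
    out = expr.drop(columns=present)
    pos = list(expr.columns).index(present[0])
    # position among remaining columns where the merged column belongs
    before = [c for c in expr.columns[:pos] if c not in present]
    out.insert(len(before), name, mean)
    return out


def drop_unexpressed(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop entities with zero abundance in every organ.

    Mute status is defined relative to other organs, so entities never
    detected anywhere do not belong to the analysis universe.
    """
    _check_expression(expr)
    return expr.loc[expr.sum(axis=1) > 0]


def _bin_values(values: pd.Series, n_bins: int) -> pd.Series:
    """Bin one organ's values: bin 1 = zeros, bins 2..n_bins equally
    populated over the nonzero values in increasing order.

    Ties are ordered deterministically by (value, entity id) and may
    straddle a boundary; when the nonzero count is not divisible, the extra
    members go to the lowest bins first.
    """
    zero = values == 0
    nonzero = values[~zero]
    m = len(nonzero)
    b = n_bins - 1
    if m == 0:
        # an organ where every universe entity is mute: all rank 1
        return pd.Series(1, index=values.index, dtype=np.int64)
    if m < b:
        raise BinningError(
            f"only {m} nonzero entities for {b} expression bins"
        )
    order = sorted(nonzero.index, key=lambda e: (nonzero[e], e))
    base, rem = divmod(m, b)
    sizes = [base + 1] * rem + [base] * (b - rem)
    ranks = pd.Series(1, index=values.index, dtype=np.int64)
    pos = 0
    for bin_idx, size in enumerate(sizes, start=2):
        for e in order[pos : pos + size]:
            ranks[e] = bin_idx
        pos += size
    return ranks


def assign_rank_column(
    expr: pd.DataFrame, organ: str, n_bins: int
) -> pd.Series:
    """Rank one organ's column of an already-universe-restricted table."""
    if organ not in expr.columns:
        raise BinningError(f"unknown organ {organ!r}")
    return _bin_values(expr[organ], n_bins)


def assign_ranks(expr: pd.DataFrame, n_bins: int = 5) -> RankTable:
    """Per-organ binning of every organ column into ``n_bins`` ranks.

    The input should already be restricted to entities detectable in at
    least one organ (see :func:`drop_unexpressed`); rank 1 in an organ then
    holds exactly the mute entities.
    """
    _check_expression(expr)
    if (expr.sum(axis=1) == 0).any():
        raise BinningError(
            "entities with zero expression everywhere must be dropped first"
        )
    ranks = pd.DataFrame(
        {organ: _bin_values(expr[organ], n_bins) for organ in expr.columns}
    )
    scale = FIVE_RANK if n_bins == 5 else ELEVEN_LEVEL
    return RankTable(ranks=ranks, scale=scale)


def assign_cross_organ_levels(
    expr: pd.DataFrame, n_bins: int = 11
) -> RankTable:
    """One global 11-level binning over all (entity, organ) values.

    Level I is assigned to every zero cell; the nonzero cells across all
    organs are pooled, sorted (deterministically by value, entity, organ)
    and cut into equally populated levels II-XI, so that levels are
    comparable between organs — a gene mute in one organ and in the top
    decile of another receives level I and level XI respectively.
    """
    _check_expression(expr)
    if (expr.sum(axis=1) == 0).any():
        raise BinningError(
            "entities with zero expression everywhere must be dropped first"
        )
    long = expr.stack()
    nonzero = long[long > 0]
    m = len(nonzero)
    b = n_bins - 1
    if m < b:
        raise BinningError(f"only {m} nonzero cells for {b} expression bins")
    order = sorted(nonzero.index, key=lambda eo: (nonzero[eo], eo))
    base, rem = divmod(m, b)
    sizes = [base + 1] * rem + [base] * (b - rem)
    levels = pd.Series(1, index=long.index, dtype=np.int64)
    pos = 0
    for bin_idx, size in enumerate(sizes, start=2):
        for key in order[pos : pos + size]:
            levels[key] = bin_idx
        pos += size
    table = levels.unstack()
    table = table.reindex(index=expr.index, columns=expr.columns)
    scale = ELEVEN_LEVEL if n_bins == 11 else FIVE_RANK
    return RankTable(ranks=table.astype(np.int64), scale=scale)


# ---------------------------------------------------------------------------
# Readers

def read_expression_table(path) -> pd.DataFrame:
    """Entities in rows, organs in columns, tab-delimited with headers."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    _check_expression(table)
    return table


def read_arm_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_age_table(path) -> pd.Series:
    """Two-column TSV (precursor_id, t) -> Series of ages in {1..4}."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise BinningError("age table needs columns (precursor_id, t)")
    ages = table.set_index(table.columns[0])[table.columns[1]].astype(int)
    ages.index.name = "precursor_id"
    ages.name = "age"
    return ages
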