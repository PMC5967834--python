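"""Repression-effect analysis via alpha/beta-condition level shifts.

A miRNA that is mute in one organ (the alpha condition) and at the top
expression rank in another (the beta condition) lets its target genes be
compared between the two regulatory regimes. For every eligible miRNA, its
targeted genes contribute ordered tuples (level under alpha, level under
beta) of cross-organ expression levels; the multiset of tuples forms an
11x11 multiplicity matrix delta, its row-normalized form delta', a
background version built from the untargeted genes, and the ratio matrix
K of targeted to background relative frequencies. Per-row shift fractions
(down / same / up under beta) quantify how often targeting coincides with
a downward shift of the target's expression level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import ELEVEN_LEVEL, FIVE_RANK, RankTable

ALL_PAIRS = "all_pairs"
CANONICAL = "canonical"

NOT_AVAILABLE = "not_available"


class RepressionError(ValueError):
    pass


@dataclass(frozen=True)
class AlphaBetaEligibility:
    """A miRNA mute (rank 1) in >= 1 organ and top-ranked (5) in another."""

    mirna_id: str
    alpha_organs: tuple[str, ...]
    beta_organs: tuple[str, ...]


@dataclass
class LevelPairMultiset:
    """Multiplicities of (alpha level, beta level) tuples on the 11x11 grid."""

    multiplicities: np.ndarray
    targeted_flag: bool

    def __post_init__(self) -> None:
        self.multiplicities = np.asarray(self.multiplicities)
        if self.multiplicities.shape != (11, 11):
            raise RepressionError("multiset must be 11x11")
        if (self.multiplicities < 0).any():
            raise RepressionError("multiplicities must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.multiplicities.sum())


@dataclass
class DeltaMatrices:
    delta: np.ndarray          # targeted multiplicities
    delta_rownorm: np.ndarray  # rows summing to 1 where nonzero
    background: np.ndarray
    background_rownorm: np.ndarray
    ratio: np.ndarray          # K; nan where the background cell is empty


@dataclass
class ShiftSummary:
    alpha_level: int
    frac_down: float | None = None
    frac_same: float | None = None
    frac_up: float | None = None
    n: float = 0.0
    status: str | None = None


def find_alpha_beta_mirnas(
    mirna_ranks: RankTable | pd.DataFrame,
) -> list[AlphaBetaEligibility]:
    """Find miRNAs exhibiting both conditions: mute somewhere, top elsewhere."""
    if isinstance(mirna_ranks, RankTable):
        if mirna_ranks.scale != FIVE_RANK:
            raise RepressionError("eligibility needs a five-rank table")
        ranks = mirna_ranks.ranks
    else:
        ranks = mirna_ranks
    eligible = []
    for mirna_id, row in ranks.iterrows():
        alpha = tuple(row.index[row == 1])
        beta = tuple(row.index[row == 5])
        if alpha and beta:
            eligible.append(AlphaBetaEligibility(str(mirna_id), alpha, beta))
    return eligible


def build_pair_multiset(
    eligible: Sequence[AlphaBetaEligibility],
    g2h: pd.DataFrame,
    cross_levels: RankTable | pd.DataFrame,
    targeted_flag: bool,
    mode: str = ALL_PAIRS,
) -> LevelPairMultiset:
    """Accumulate (alpha level, beta level) tuples over eligible miRNAs.

    For each eligible miRNA and each gene with the requested targeting
    status, one tuple is added per (alpha organ, beta organ) combination
    (``mode="all_pairs"``, the multiset reading of the existential
    quantifier); ``mode="canonical"`` instead picks a single pair — the
    first alpha and first beta organ in the rank table's column order — per
    (miRNA, gene).
    """
    if mode not in (ALL_PAIRS, CANONICAL):
        raise RepressionError(f"unknown mode {mode!r}")
    if isinstance(cross_levels, RankTable):
        if cross_levels.scale != ELEVEN_LEVEL:
            raise RepressionError("cross-organ levels must be eleven-level")
        levels = cross_levels.ranks
    else:
        levels = cross_levels
    counts = np.zeros((11, 11), dtype=np.int64)
    for el in eligible:
        if el.mirna_id not in g2h.columns:
            raise RepressionError(f"precursor {el.mirna_id!r} missing from G2H")
        targeted = g2h[el.mirna_id].astype(bool)
        genes = targeted.index[targeted == bool(targeted_flag)]
        organ_pairs = (
            list(product(el.alpha_organs, el.beta_organs))
            if mode == ALL_PAIRS
            else [(el.alpha_organs[0], el.beta_organs[0])]
        )
        for z_alpha, z_beta in organ_pairs:
            for organ in (z_alpha, z_beta):
                if organ not in levels.columns:
                    raise RepressionError(f"no levels for organ {organ!r}")
            sub = levels.loc[genes, [z_alpha, z_beta]]
            if sub.isna().any().any():
                bad = sub.index[sub.isna().any(axis=1)][:5].tolist()
                raise RepressionError(
                    f"genes missing a level in {z_alpha}/{z_beta}: {bad!r}"
                )
            a = sub[z_alpha].to_numpy(dtype=np.int64) - 1
            b = sub[z_beta].to_numpy(dtype=np.int64) - 1
            np.add.at(counts, (a, b), 1)
    return LevelPairMultiset(multiplicities=counts, targeted_flag=targeted_flag)


def _row_normalize(matrix: np.ndarray) -> np.ndarray:
    out = np.zeros_like(matrix, dtype=float)
    sums = matrix.sum(axis=1)
    nz = sums > 0
    out[nz] = matrix[nz] / sums[nz, None]
    return out


def normalize_and_ratio(
    targeted: LevelPairMultiset, background: LevelPairMultiset
) -> DeltaMatrices:
    """Row-normalize both multisets and form the targeted/background ratio.

    K[alpha, beta] divides the targeted cell's global relative frequency by
    the background's; cells with an empty background are undefined (NaN)."""
    delta = targeted.multiplicities.astype(float)
    bg = background.multiplicities.astype(float)
    if delta.sum() == 0:
        raise RepressionError("all-zero targeted multiset")
    ratio = np.full((11, 11), np.nan)
    if bg.sum() > 0:
        rel_t = delta / delta.sum()
        rel_b = np.where(bg > 0, bg / bg.sum(), np.nan)
        ratio = rel_t / rel_b
    return DeltaMatrices(
        delta=delta,
        delta_rownorm=_row_normalize(delta),
        background=bg,
        background_rownorm=_row_normalize(bg),
        ratio=ratio,
    )


def shift_fractions(delta_row: Sequence[float], alpha_level: int) -> ShiftSummary:
    """Fractions of mass below / at / above the alpha level within one row.

    At alpha level XI an upward shift is structurally impossible (no level
    above XI), so only down/same fractions can be nonzero there.
    """
    row = np.asarray(delta_row, dtype=float)
    if row.shape != (11,):
        raise RepressionError("a delta row has 11 beta levels")
    if not 1 <= alpha_level <= 11:
        raise RepressionError("alpha_level must be in 1..11")
    total = row.sum()
    if total <= 0:
        return ShiftSummary(alpha_level=alpha_level, status=NOT_AVAILABLE)
    k = alpha_level - 1
    return ShiftSummary(
        alpha_level=alpha_level,
        frac_down=float(row[:k].sum() / total),
        frac_same=float(row[k] / total),
        frac_up=float(row[k + 1 :].sum() / total),
        n=float(total),
    )


def compare_shift_proportions(
    frac1: float, n1: int, frac2: float, n2: int
) -> float:
    """Two-sided comparison of two shift fractions.

    Uses the pooled-variance normal approximation for the difference of two
    proportions, falling back to Fisher's exact test when any pooled
    expected cell is below 5. This comparison is a design choice of the
    package, not a reproduction of any particular published test.
    """
    for frac, n in ((frac1, n1), (frac2, n2)):
        if n < 1:
            raise RepressionError("n must be >= 1")
        if not 0 <= frac <= 1:
            raise RepressionError("fractions must lie in [0, 1]")
    x1, x2 = round(frac1 * n1), round(frac2 * n2)
    pooled = (x1 + x2) / (n1 + n2)
    expected = [n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled)]
    if min(expected) < 5:
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if pooled in (0.0, 1.0):
        return 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def matrix_frame(matrix: np.ndarray) -> pd.DataFrame:
    """11x11 matrix as a DataFrame with Roman-numeral level labels."""
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI"]
    return pd.DataFrame(matrix, index=numerals, columns=numerals)
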