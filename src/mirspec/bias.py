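"""Targeting-bias statistics, avoidance/preference indices and tests.

The central object is a contingency table of targeting occurrences: within
one organ and one miRNA age class, cell (l, j) counts the (gene, precursor)
pairs in which a precursor of expression rank j has a predicted site in a
gene of expression level l. Under independence of miRNA and target
expression the expected count is the product of the marginals; each cell's
deviation is summarized by the Pearson statistic C = (O - E)^2 / E and
reported as the signed bias

    B = -log10 P(X > C),  X ~ chi-square(1),

positive when the cell is over-represented (O >= E) and negative when
under-represented. From the five-rank table two scalar indices are read
off the top miRNA rank:

* avoidance index A — how strongly the most highly expressed miRNAs avoid
  the most highly expressed genes (requires B[top gene, mute miRNA] > 0 and
  B[top gene, top miRNA] < 0, otherwise "not in order");
* preference index H — the height of the Λ-shaped preference for genes of
  intermediate expression.

Indices of two miRNA age classes are compared per organ with an exact
two-sided Wilcoxon signed-rank test ("not in order" entries score a pseudo
value of 0, organs where both sides are out of order are excluded), and an
expression-vs-age trend is assessed with a Jonckheere-Terpstra test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FIVE_RANK = "five_rank"
ELEVEN_LEVEL = "eleven_level"

NOT_IN_ORDER = "not_in_order"
NOT_AVAILABLE = "not_available"

LAMBDA = "lambda"
VEE = "vee"
NEITHER = "neither"

#: Tail probabilities below this are floored so the bias stays finite.
_TAIL_FLOOR = 1e-300
_BIAS_CAP = 300.0


class BiasError(ValueError):
    pass


@dataclass
class OccurrenceTable:
    """Observed targeting occurrences, gene bins x 5 miRNA ranks."""

    counts: np.ndarray
    gene_scale: str
    organ: str | None = None
    age: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected_rows = 11 if self.gene_scale == ELEVEN_LEVEL else 5
        if self.counts.shape != (expected_rows, 5):
            raise BiasError(
                f"{self.gene_scale} table must be {expected_rows}x5, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise BiasError("occurrence counts must be nonnegative")


@dataclass
class ExpectedTable:
    expected: np.ndarray  # E, same shape as O
    probs: np.ndarray     # P = E / W
    total: float          # W


@dataclass
class BiasTable:
    chi2: np.ndarray           # C >= 0; nan where undefined
    bias: np.ndarray           # signed -log10 tail probability
    not_available: np.ndarray  # cells with E = 0 < O
    capped: np.ndarray         # cells where the tail hit the floating floor


@dataclass
class IndexValue:
    """A nonnegative index value or an explanatory status."""

    value: float | None = None
    status: str | None = None
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.value is None) == (self.status is None):
            raise BiasError("exactly one of value/status must be set")

    @property
    def defined(self) -> bool:
        return self.value is not None

    def pseudo(self) -> float:
        """Value with "not in order" mapped to the pseudo value 0."""
        return self.value if self.value is not None else 0.0


def count_occurrences(
    g2h: pd.DataFrame,
    gene_levels: pd.Series,
    mirna_ranks: pd.Series,
    ages: pd.Series,
    age: int,
    n_gene_bins: int = 11,
    n_mirna_bins: int = 5,
    organ: str | None = None,
) -> OccurrenceTable:
    """Count (gene, precursor) targeting pairs of one age class into a
    gene-level x miRNA-rank table for one organ.

    ``gene_levels`` and ``mirna_ranks`` are that organ's columns of the
    binned tables; every gene/precursor of ``g2h`` must carry a level/rank.
    """
    missing_g = [g for g in g2h.index if g not in gene_levels.index]
    missing_h = [
        h for h in g2h.columns
        if h not in mirna_ranks.index or h not in ages.index
    ]
    if missing_g or missing_h:
        raise BiasError(
            f"entities without rank/level/age: genes {missing_g[:5]!r}, "
            f"precursors {missing_h[:5]!r}"
        )
    levels = gene_levels.loc[g2h.index].to_numpy()
    ranks = mirna_ranks.loc[g2h.columns].to_numpy()
    age_mask = ages.loc[g2h.columns].to_numpy() == age
    left = np.zeros((n_gene_bins, len(levels)))
    left[levels - 1, np.arange(len(levels))] = 1.0
    right = np.zeros((len(ranks), n_mirna_bins))
    idx = np.arange(len(ranks))[age_mask]
    right[idx, ranks[age_mask] - 1] = 1.0
    counts = left @ g2h.to_numpy(dtype=float) @ right
    scale = ELEVEN_LEVEL if n_gene_bins == 11 else FIVE_RANK
    return OccurrenceTable(counts=counts, gene_scale=scale, organ=organ, age=age)


def convert_levels_to_ranks(o: OccurrenceTable) -> OccurrenceTable:
    """Smooth an 11-level table to five gene ranks.

    Row 1 keeps the mute-gene level I; rows 2-4 are the arithmetic means of
    levels II-IV, V-VII and VIII-X; row 5 keeps the top level XI.
    """
    if o.gene_scale != ELEVEN_LEVEL:
        raise BiasError("conversion expects an eleven-level table")
    c = o.counts
    five = np.vstack(
        [
            c[0],
            c[1:4].mean(axis=0),
            c[4:7].mean(axis=0),
            c[7:10].mean(axis=0),
            c[10],
        ]
    )
    return OccurrenceTable(
        counts=five, gene_scale=FIVE_RANK, organ=o.organ, age=o.age
    )


def expected_counts(o: OccurrenceTable) -> ExpectedTable:
    """Independence expectation from the table's marginals.

    E[i, j] = (row_i sum)(col_j sum) / W with W the grand total; P = E / W.
    """
    counts = o.counts
    total = counts.sum()
    if total <= 0:
        raise BiasError("empty table")
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    return ExpectedTable(expected=expected, probs=expected / total, total=total)


def signed_bias(
    observed: np.ndarray | OccurrenceTable, expected: np.ndarray | ExpectedTable
) -> BiasTable:
    """Per-cell Pearson statistic and signed -log10 chi-square(1) tail.

    Cells with E = 0 but O > 0 are flagged not-available; E = O = 0 gives
    bias 0. Tail probabilities are floored at 1e-300 (bias capped at 300)
    and such cells flagged as capped.
    """
    O = observed.counts if isinstance(observed, OccurrenceTable) else np.asarray(observed, float)
    E = expected.expected if isinstance(expected, ExpectedTable) else np.asarray(expected, float)
    if O.shape != E.shape:
        raise BiasError("observed/expected shape mismatch")
    chi2 = np.full(O.shape, np.nan)
    bias = np.full(O.shape, np.nan)
    not_available = (E == 0) & (O > 0)
    zero_zero = (E == 0) & (O == 0)
    ok = E > 0
    with np.errstate(over="ignore"):  # inf chi2 hits the cap below
        chi2[ok] = (O[ok] - E[ok]) ** 2 / E[ok]
    chi2[zero_zero] = 0.0
    tail = stats.chi2.sf(chi2[ok], df=1)
    capped_ok = tail < _TAIL_FLOOR
    tail = np.maximum(tail, _TAIL_FLOOR)
    magnitude = np.minimum(-np.log10(tail), _BIAS_CAP)
    sign = np.where(O[ok] >= E[ok], 1.0, -1.0)
    bias[ok] = sign * magnitude
    bias[zero_zero] = 0.0
    capped = np.zeros(O.shape, dtype=bool)
    capped[ok] = capped_ok
    return BiasTable(chi2=chi2, bias=bias, not_available=not_available, capped=capped)


def avoidance_index(bias_table: BiasTable) -> IndexValue:
    """Avoidance of the most highly expressed genes by the most highly
    expressed miRNAs: A = C[5,5] + C[5,1], defined only when the mute-miRNA
    bias at the top gene rank is positive and the top-top bias negative."""
    B, C = bias_table.bias, bias_table.chi2
    if B.shape != (5, 5):
        raise BiasError("avoidance index needs a five-rank table")
    b_mute, b_top = B[4, 0], B[4, 4]
    if not (np.isfinite(b_mute) and np.isfinite(b_top)):
        return IndexValue(status=NOT_AVAILABLE)
    if b_mute > 0 and b_top < 0:
        return IndexValue(
            value=float(C[4, 4] + C[4, 0]),
            components={"C_top_top": float(C[4, 4]), "C_top_mute": float(C[4, 0])},
        )
    return IndexValue(status=NOT_IN_ORDER)


def shape_call(b_top_column: Sequence[float]) -> str:
    """Convexity of the top-miRNA-rank bias across the five gene ranks.

    Λ ("lambda") if every inner bias (gene ranks 2-4) exceeds both outer
    ones (ranks 1 and 5); V ("vee") for the mirrored condition; otherwise
    "neither". The two calls are mutually exclusive by construction.
    """
    b = np.asarray(b_top_column, dtype=float)
    if b.shape != (5,) or not np.isfinite(b).all():
        raise BiasError("shape call needs 5 finite bias values")
    inner, outer = b[1:4], b[[0, 4]]
    if inner.min() > outer.max():
        return LAMBDA
    if inner.max() < outer.min():
        return VEE
    return NEITHER


def preference_index(
    b_top_column: Sequence[float], c_top_column: Sequence[float]
) -> IndexValue:
    """Height of the Λ: H = H_rise + H_dive.

    H_rise is the Pearson statistic at the strongest inner (gene ranks 2-4)
    bias; H_dive at the larger of the two outer biases (ranks 1 and 5).
    Defined only when the best inner bias is positive and both outer biases
    negative; argmax ties resolve to the smaller gene rank.
    """
    b = np.asarray(b_top_column, dtype=float)
    c = np.asarray(c_top_column, dtype=float)
    if b.shape != (5,) or c.shape != (5,):
        raise BiasError("preference index needs 5 bias and 5 chi2 values")
    if not (np.isfinite(b).all() and np.isfinite(c).all()):
        return IndexValue(status=NOT_AVAILABLE)
    inner_idx = 1 + int(np.argmax(b[1:4]))      # first max wins ties
    outer_idx = [0, 4][int(np.argmax(b[[0, 4]]))]
    if b[inner_idx] > 0 and b[outer_idx] < 0:
        return IndexValue(
            value=float(c[inner_idx] + c[outer_idx]),
            components={
                "H_rise": float(c[inner_idx]),
                "H_dive": float(c[outer_idx]),
            },
        )
    return IndexValue(status=NOT_IN_ORDER)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact) and Jonckheere-Terpstra tests

@dataclass
class TestResult:
    statistic: float | None = None
    p: float | None = None
    n: int = 0
    status: str | None = None

    @property
    def available(self) -> bool:
        return self.p is not None


def _signed_rank_distribution(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Exact null distribution of the negative-rank sum on the doubled-rank
    integer grid, by dynamic programming over all 2^n sign assignments."""
    total = int(sum(doubled_ranks))
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    return dist


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_limit: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes get mid-ranks. The null
    distribution is enumerated exactly for n <= ``exact_limit`` (dynamic
    programming over sign assignments, equivalent to the full 2^n
    enumeration); larger samples use the normal approximation with tie
    correction and no continuity correction.
    """
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    if n < 1:
        return TestResult(status=NOT_AVAILABLE)
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_neg = float(ranks[d < 0].sum())
    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_neg))
        p_le = float(dist[: w2 + 1].sum())
        p_ge = float(dist[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if var <= 0:
            return TestResult(statistic=w_neg, p=1.0, n=n)
        z = (w_neg - mean) / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=w_neg, p=p, n=n)


def _pseudo_pairs(
    index_a: Sequence[IndexValue | float | None],
    index_b: Sequence[IndexValue | float | None],
) -> list[tuple[float, float]]:
    """Apply the pseudo-0 / exclusion rules to paired per-organ indices."""

    def coerce(v) -> float | None:
        if v is None:
            return None
        if isinstance(v, IndexValue):
            return v.value if v.defined else None
        if isinstance(v, float) and math.isnan(v):
            return None
        return float(v)

    if len(index_a) != len(index_b):
        raise BiasError("paired index lists must share the organ list")
    pairs = []
    for va, vb in zip(index_a, index_b):
        a, b = coerce(va), coerce(vb)
        if a is None and b is None:
            continue  # both out of order: organ excluded
        pairs.append((a if a is not None else 0.0, b if b is not None else 0.0))
    return pairs


def paired_signed_rank_test(
    index_a: Sequence[IndexValue | float | None],
    index_b: Sequence[IndexValue | float | None],
) -> TestResult:
    """Compare per-organ indices of two miRNA age classes.

    An undefined ("not in order" / missing) index on exactly one side is
    scored as the pseudo value 0; organs undefined on both sides are
    excluded. The remaining paired differences enter the exact two-sided
    Wilcoxon signed-rank test.
    """
    pairs = _pseudo_pairs(index_a, index_b)
    if not pairs:
        return TestResult(status=NOT_AVAILABLE)
    diffs = [a - b for a, b in pairs]
    return wilcoxon_signed_rank(diffs)


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """Sum of between-group Mann-Whitney counts over ordered group pairs,
    ties counted half."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(j)


def _multinomial(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    out = 1
    for s in sizes:
        out *= math.comb(total, s)
        total -= s
    return out


def jonckheere_terpstra_test(
    groups: Sequence[Sequence[float]],
    alternative: str = "increasing",
    max_exact: int = 200_000,
) -> TestResult:
    """Jonckheere-Terpstra trend test across age-ordered groups.

    The statistic sums Mann-Whitney counts over all ordered group pairs
    (ties half-weighted). For small samples (at most ``max_exact`` distinct
    group assignments) the permutation null is enumerated exactly;
    otherwise a normal approximation with tie correction is used. The
    default alternative is one-sided in the stated trend direction
    ("increasing" with group order); "decreasing" and "two-sided" are
    available.
    """
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise BiasError(f"unknown alternative {alternative!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise BiasError("need >= 2 nonempty groups")
    sizes = [a.size for a in arrays]
    observed = _jt_statistic(arrays)
    n_total = sum(sizes)
    n_arrangements = _multinomial(sizes)
    if n_arrangements <= max_exact:
        pooled = np.concatenate(arrays)
        count_ge = 0
        count_le = 0
        indices = list(range(n_total))

        def assignments(remaining: list[int], size_idx: int, chosen: list[np.ndarray]):
            nonlocal count_ge, count_le
            if size_idx == len(sizes) - 1:
                grouping = chosen + [pooled[remaining]]
                j = _jt_statistic(grouping)
                if j >= observed - 1e-9:
                    count_ge += 1
                if j <= observed + 1e-9:
                    count_le += 1
                return
            for combo in itertools.combinations(remaining, sizes[size_idx]):
                rest = [i for i in remaining if i not in combo]
                assignments(rest, size_idx + 1, chosen + [pooled[list(combo)]])

        assignments(indices, 0, [])
        p_ge = count_ge / n_arrangements
        p_le = count_le / n_arrangements
    else:
        mean = (n_total**2 - sum(s**2 for s in sizes)) / 4.0
        pooled = np.concatenate(arrays)
        _, ties = np.unique(pooled, return_counts=True)
        n = n_total
        s2 = sum(s * (s - 1) * (2 * s + 5) for s in sizes)
        t2 = sum(t * (t - 1) * (2 * t + 5) for t in ties)
        term1 = (n * (n - 1) * (2 * n + 5) - s2 - t2) / 72.0
        term2 = (
            sum(s * (s - 1) * (s - 2) for s in sizes)
            * sum(t * (t - 1) * (t - 2) for t in ties)
            / (36.0 * n * (n - 1) * (n - 2))
        )
        term3 = (
            sum(s * (s - 1) for s in sizes)
            * sum(t * (t - 1) for t in ties)
            / (8.0 * n * (n - 1))
        )
        var = term1 + term2 + term3
        if var <= 0:
            return TestResult(statistic=observed, p=1.0, n=n_total)
        z = (observed - mean) / math.sqrt(var)
        p_ge = float(stats.norm.sf(z))
        p_le = float(stats.norm.cdf(z))
    if alternative == "increasing":
        p = p_ge
    elif alternative == "decreasing":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(statistic=observed, p=min(1.0, p), n=n_total)


# ---------------------------------------------------------------------------
# Tidy output helpers

def bias_frame(
    o: OccurrenceTable, e: ExpectedTable, b: BiasTable
) -> pd.DataFrame:
    """Tidy per-cell table: gene_rank, mirna_rank, observed, expected,
    chi2, bias (one row per cell)."""
    n_rows, n_cols = o.counts.shape
    rows = []
    for i in range(n_rows):
        for j in range(n_cols):
            rows.append(
                {
                    "organ": o.organ,
                    "age": o.age,
                    "gene_rank": i + 1,
                    "mirna_rank": j + 1,
                    "observed": o.counts[i, j],
                    "expected": e.expected[i, j],
                    "chi2": b.chi2[i, j],
                    "bias": b.bias[i, j],
                }
            )
    return pd.DataFrame(rows)
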