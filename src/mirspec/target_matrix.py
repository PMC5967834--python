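"""Gene-by-miRNA targeting matrices from predicted target-site tables.

This module ingests tab-delimited hit tables from seed-match target
predictors in two dialects — a context-score dialect (site efficacy scored
by a dimensionless context score, more negative = stronger) and an
accessibility dialect (site accessibility scored by a free-energy
difference ddG, more negative = stronger) — filters them by seed class and
score, collapses overlapping sites into nonredundant ones, and builds the
three matrices that drive the downstream analysis:

* ``g2m``  — genes x mature miRNAs, number of nonredundant predicted sites;
* ``m2h``  — mature miRNAs x precursor (hairpin) miRNAs, 0/1 membership;
* ``G2H``  — genes x precursors, the 0/1 indicator ``1(g2m @ m2h > 0)``.

All site coordinates are 1-based inclusive positions within the 3' UTR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXT_SCORE = "context_score"
ACCESSIBILITY = "accessibility"

#: Allowed seed-match classes per dialect: exact 7-mer (positions 2-8) or
#: 8-mer matches; wobble-containing classes are excluded upstream.
SITE_TYPES: dict[str, frozenset[str]] = {
    CONTEXT_SCORE: frozenset({"7mer-m8", "8mer-1a"}),
    ACCESSIBILITY: frozenset({"7:0:0", "8:0:0"}),
}


class TargetMatrixError(ValueError):
    """Raised on malformed hits, unknown ids or dimension mismatches."""


@dataclass(frozen=True)
class TargetSiteHit:
    """One predicted target site of a mature miRNA within a gene's 3' UTR."""

    gene_id: str
    mature_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, end >= start
    site_type: str
    score: float

    def __post_init__(self) -> None:
        if self.start < 1:
            raise TargetMatrixError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise TargetMatrixError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HitFilterSpec:
    """Score filter for one dialect: a hit is kept iff ``score < threshold``."""

    dialect: str
    threshold: float
    named_set: str = "custom"

    def __post_init__(self) -> None:
        if self.dialect not in SITE_TYPES:
            raise TargetMatrixError(f"unknown dialect {self.dialect!r}")
        if not math.isfinite(self.threshold):
            raise TargetMatrixError("threshold must be finite")


#: Named stringency sets. The context-score triple follows the stricter of
#: the two threshold conventions in circulation (-0.4/-0.5/-0.6); the
#: accessibility triple was calibrated so each set matches the hit count of
#: the corresponding context-score set.
NAMED_FILTER_SETS: dict[str, HitFilterSpec] = {
    "C010": HitFilterSpec(CONTEXT_SCORE, -0.4, "C010"),
    "C020": HitFilterSpec(CONTEXT_SCORE, -0.5, "C020"),
    "C030": HitFilterSpec(CONTEXT_SCORE, -0.6, "C030"),
    "P010": HitFilterSpec(ACCESSIBILITY, -0.96, "P010"),
    "P020": HitFilterSpec(ACCESSIBILITY, -3.69, "P020"),
    "P030": HitFilterSpec(ACCESSIBILITY, -9.49, "P030"),
}


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Per-transcript annotation used to choose one transcript per gene."""

    gene_id: str
    transcript_id: str
    cds_length: int
    coding_end: int  # strand-oriented; larger = further downstream
    utr3_length: int
    transcript_length: int

    def __post_init__(self) -> None:
        for name in ("cds_length", "utr3_length", "transcript_length"):
            if getattr(self, name) < 0:
                raise TargetMatrixError(f"{name} must be >= 0")


def select_representative_transcript(
    annotations: Sequence[TranscriptAnnotation],
) -> str:
    """Pick one representative transcript for a gene.

    Lexicographic priority: longest CDS, then most-downstream coding end,
    then longest 3' UTR, then longest transcript; any residual tie is
    broken deterministically on the smallest transcript id.
    """
    if not annotations:
        raise TargetMatrixError("no transcripts")
    best = min(
        annotations,
        key=lambda a: (
            -a.cds_length,
            -a.coding_end,
            -a.utr3_length,
            -a.transcript_length,
            a.transcript_id,
        ),
    )
    return best.transcript_id


def filter_hits(
    hits: Iterable[TargetSiteHit],
    spec: HitFilterSpec,
    utr3_length: int | Mapping[str, int] | None = None,
) -> list[TargetSiteHit]:
    """Keep hits of an allowed seed class with score strictly below threshold.

    For the accessibility dialect the whole seed-matched sequence must lie
    within the 3' UTR, so ``end <= utr3_length`` is additionally enforced
    (``utr3_length`` may be a scalar or a mapping gene_id -> length);
    sites overhanging into the flanking sequence are dropped. Input order
    is preserved.
    """
    allowed = SITE_TYPES[spec.dialect]
    other = set().union(*(v for k, v in SITE_TYPES.items() if k != spec.dialect))
    kept: list[TargetSiteHit] = []
    for hit in hits:
        if hit.site_type in other and hit.site_type not in allowed:
            raise TargetMatrixError(
                f"hit {hit.gene_id}/{hit.mature_id} has site type "
                f"{hit.site_type!r} from a different dialect than {spec.dialect!r}"
            )
        if hit.site_type not in allowed:
            continue
        if not hit.score < spec.threshold:
            continue
        if spec.dialect == ACCESSIBILITY and utr3_length is not None:
            if isinstance(utr3_length, Mapping):
                if hit.gene_id not in utr3_length:
                    raise TargetMatrixError(
                        f"no 3' UTR length for gene {hit.gene_id!r}"
                    )
                limit = utr3_length[hit.gene_id]
            else:
                limit = int(utr3_length)
            if hit.end > limit:
                continue
        kept.append(hit)
    return kept


def _overlaps(a: TargetSiteHit, b: TargetSiteHit) -> bool:
    return max(a.start, b.start) <= min(a.end, b.end)


def remove_overlapping_sites(
    hits: Sequence[TargetSiteHit],
) -> list[TargetSiteHit]:
    """Collapse overlapping sites of one (gene, mature miRNA) pair.

    Scanning 5'->3' by start position, a site overlapping an
    already-retained site is removed; so in a chain of overlaps the
    bridging middle site is removed and the two outer ones are kept, and in
    a stack of overlaps only the most-5' site survives. Equal-start ties
    keep the longer site first (then smaller site type / score for
    determinism). Idempotent.
    """
    if not hits:
        return []
    key = {(h.gene_id, h.mature_id) for h in hits}
    if len(key) > 1:
        raise TargetMatrixError(
            "remove_overlapping_sites expects hits of a single (gene, mature) pair"
        )
    ordered = sorted(
        hits, key=lambda h: (h.start, -h.length, h.site_type, h.score)
    )
    kept: list[TargetSiteHit] = []
    for hit in ordered:
        if not kept or not _overlaps(kept[-1], hit):
            kept.append(hit)
    return kept


def deduplicate_hits(hits: Iterable[TargetSiteHit]) -> list[TargetSiteHit]:
    """Apply overlap removal within every (gene, mature) group."""
    groups: dict[tuple[str, str], list[TargetSiteHit]] = {}
    for hit in hits:
        groups.setdefault((hit.gene_id, hit.mature_id), []).append(hit)
    out: list[TargetSiteHit] = []
    for group in groups.values():
        out.extend(remove_overlapping_sites(group))
    return out


def build_gene_to_mature(
    hits: Iterable[TargetSiteHit],
    genes: Sequence[str] | None = None,
    matures: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count nonredundant sites into a genes x mature-miRNAs integer matrix.

    ``genes`` / ``matures`` declare the row/column universes; hits outside a
    declared universe raise an error naming the offenders. If a universe is
    omitted it is derived from the hits themselves.
    """
    hits = list(hits)
    hit_genes = [h.gene_id for h in hits]
    hit_matures = [h.mature_id for h in hits]
    if genes is None:
        genes = sorted(set(hit_genes))
    if matures is None:
        matures = sorted(set(hit_matures))
    unknown_g = sorted(set(hit_genes) - set(genes))
    unknown_m = sorted(set(hit_matures) - set(matures))
    if unknown_g or unknown_m:
        raise TargetMatrixError(
            f"hits reference ids outside the declared universes: "
            f"genes {unknown_g!r}, matures {unknown_m!r}"
        )
    counts = pd.DataFrame(
        np.zeros((len(genes), len(matures)), dtype=np.int64),
        index=pd.Index(genes, name="gene_id"),
        columns=pd.Index(matures, name="mature_id"),
    )
    for g, m in zip(hit_genes, hit_matures):
        counts.loc[g, m] += 1
    return counts


def compose_gene_to_precursor(
    g2m: pd.DataFrame, m2h: pd.DataFrame
) -> pd.DataFrame:
    """Bridge mature miRNAs: ``G2H[g, h] = 1`` iff any mature of precursor h
    has at least one site in gene g (multiple sites still count as 1, and a
    mature shared by several precursors marks all of them)."""
    if set(g2m.columns) != set(m2h.index):
        raise TargetMatrixError(
            "dimension mismatch: g2m columns and m2h rows must hold the same "
            "mature miRNA universe"
        )
    m2h = m2h.reindex(index=g2m.columns)
    if (g2m.values < 0).any() or ~np.isin(m2h.values, (0, 1)).all():
        raise TargetMatrixError("g2m must be nonnegative and m2h binary")
    product = g2m.values.astype(np.int64) @ m2h.values.astype(np.int64)
    indicator = (product > 0).astype(np.int8)
    return pd.DataFrame(
        indicator,
        index=g2m.index.rename("gene_id"),
        columns=m2h.columns.rename("precursor_id"),
    )


def calibrate_threshold(
    candidate_hits: Sequence[TargetSiteHit],
    reference_count: int,
    named_set: str = "calibrated",
) -> HitFilterSpec:
    """Choose the accessibility-score threshold whose retained-hit count is
    closest to ``reference_count`` (ties toward the smaller, stricter count).

    Candidates must already be seed-filtered and overlap-removed; the
    threshold is a strict upper bound on the score, so only counts at which
    the sorted score sequence strictly increases are achievable.
    """
    if reference_count < 0:
        raise TargetMatrixError("reference_count must be >= 0")
    scores = sorted(h.score for h in candidate_hits)
    if not scores:
        if reference_count > 0:
            warnings.warn(
                "no candidate hits to calibrate against a positive reference "
                "count; returning threshold -inf",
                stacklevel=2,
            )
        # Effectively -inf while keeping the spec finite.
        return HitFilterSpec(ACCESSIBILITY, -1e308, named_set)
    m = len(scores)
    # Achievable counts k: 0, every k with scores[k-1] < scores[k], and m.
    achievable: list[tuple[int, float]] = [(0, scores[0])]
    for k in range(1, m):
        if scores[k - 1] < scores[k]:
            achievable.append((k, scores[k]))
    achievable.append((m, math.nextafter(scores[-1], math.inf)))
    best_k, best_thr = min(
        achievable, key=lambda kt: (abs(kt[0] - reference_count), kt[0])
    )
    return HitFilterSpec(ACCESSIBILITY, best_thr, named_set)


# ---------------------------------------------------------------------------
# Tab-delimited readers / writers

#: Default column mapping for context-score predictor output.
CONTEXT_COLUMNS = {
    "gene_id": "gene_id",
    "mature_id": "mirna",
    "site_type": "site_type",
    "start": "utr_start",
    "end": "utr_end",
    "score": "context_score",
}

#: Default column mapping for accessibility predictor output.
ACCESSIBILITY_COLUMNS = {
    "gene_id": "utr",
    "mature_id": "microrna",
    "site_type": "seed",
    "start": "start",
    "end": "end",
    "score": "ddg",
}


def _read_hits(
    path, columns: Mapping[str, str], offset: int = 0
) -> list[TargetSiteHit]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in columns.values() if c not in table.columns]
    if missing:
        raise TargetMatrixError(f"hit table {path} lacks columns {missing}")
    hits = []
    for row in table.itertuples(index=False):
        rec = {k: getattr(row, columns[k]) for k in columns}
        hits.append(
            TargetSiteHit(
                gene_id=str(rec["gene_id"]),
                mature_id=str(rec["mature_id"]),
                start=int(rec["start"]) - offset,
                end=int(rec["end"]) - offset,
                site_type=str(rec["site_type"]),
                score=float(rec["score"]),
            )
        )
    return hits


def read_context_hits(
    path, columns: Mapping[str, str] | None = None
) -> list[TargetSiteHit]:
    """Read a context-score dialect hit table (coordinates already within
    the 3' UTR, 1-based inclusive)."""
    return _read_hits(path, columns or CONTEXT_COLUMNS)


def read_accessibility_hits(
    path,
    columns: Mapping[str, str] | None = None,
    flank_up: int = 0,
) -> list[TargetSiteHit]:
    """Read an accessibility dialect hit table.

    ``flank_up`` is subtracted from both coordinates so that positions
    reported on a flank-extended UTR are normalized back to 1-based
    positions within the plain 3' UTR.
    """
    return _read_hits(path, columns or ACCESSIBILITY_COLUMNS, offset=flank_up)


def write_hit_table(
    hits: Sequence[TargetSiteHit],
    path,
    dialect: str,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write hits as a tab-delimited table in the given dialect's layout."""
    if columns is None:
        columns = CONTEXT_COLUMNS if dialect == CONTEXT_SCORE else ACCESSIBILITY_COLUMNS
    frame = pd.DataFrame(
        {
            columns["gene_id"]: [h.gene_id for h in hits],
            columns["mature_id"]: [h.mature_id for h in hits],
            columns["site_type"]: [h.site_type for h in hits],
            columns["start"]: [h.start for h in hits],
            columns["end"]: [h.end for h in hits],
            columns["score"]: [h.score for h in hits],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Serialize a matrix as TSV: header row of column ids, first column of
    row ids."""
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
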