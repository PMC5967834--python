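"""Synthetic fixture generation with a known targeting-bias ground truth.

The generator emulates the statistical structure of the real inputs:
heavy-tailed nonnegative expression (log-normal) with organ-specific
dropout ("mute" entries, more likely for lowly expressed entities), a
four-class miRNA age labeling in which older classes are more highly
expressed, a mature-to-precursor map with one or two arms per precursor,
and gene x precursor targeting indicators whose joint distribution over
(gene level x miRNA rank) either satisfies independence or carries a
planted avoidance (depleted top-top cell) and/or Λ-shaped preference
(enriched intermediate-gene cells at the top miRNA rank).

Everything is driven by one integer seed; fixed per-purpose substreams
keep outputs byte-identical under a fixed seed even if new outputs are
added later.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import target_matrix as tm

INDEPENDENCE = "independence"
AVOIDANCE = "avoidance"
LAMBDA = "lambda"
AVOIDANCE_LAMBDA = "avoidance_lambda"

_PROFILES = (INDEPENDENCE, AVOIDANCE, LAMBDA, AVOIDANCE_LAMBDA)

# Substream offsets: one per purpose, never reused.
_STREAM_AGES = 1
_STREAM_MIRNA_EXPR = 2
_STREAM_GENE_EXPR = 3
_STREAM_ARMS = 4
_STREAM_PAIRS = 5
_STREAM_SITES = 6
_STREAM_UTR = 7


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-like default conditions for the synthetic fixture bundle."""

    n_genes: int = 600
    n_precursors: int = 150
    n_mature_per_precursor: int = 2
    organs: tuple[str, ...] = (
        "brain", "heart", "kidney", "liver", "ovary", "testis",
    )
    seed: int = 0
    # log-normal expression model (natural-log scale) + per-organ dropout
    meanlog: float = 2.0
    sdlog: float = 2.0
    organ_sdlog: float = 0.5
    zero_inflation: float = 0.25
    # age labeling: four classes, class 1 = oldest; older classes are both
    # more common among well-expressed miRNAs and more highly expressed
    age_mixture: tuple[float, float, float, float] = (0.30, 0.25, 0.25, 0.20)
    age_expression_shift: float = 0.8  # meanlog increment per step older
    # planted targeting structure
    bias_profile: str = INDEPENDENCE
    strength: float = 0.5
    age_strength: tuple[float, float, float, float] = (1.0, 0.5, 0.25, 0.25)
    n_target_pairs: int = 6000
    overlap_rate: float = 0.15
    extra_site_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.bias_profile not in _PROFILES:
            raise SyntheticError(f"unknown bias profile {self.bias_profile!r}")
        if not 0 <= self.strength <= 1:
            raise SyntheticError("strength must lie in [0, 1]")
        if abs(sum(self.age_mixture) - 1.0) > 1e-9:
            raise SyntheticError("age mixture proportions must sum to 1")
        if self.n_mature_per_precursor not in (1, 2):
            raise SyntheticError("1 or 2 mature miRNAs per precursor")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _quantile_classes(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Split values into n_classes groups of (near-)equal size by sort
    order, class 1 = lowest; extras go to the lowest classes first."""
    n = values.size
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, n_classes)
    sizes = [base + 1] * rem + [base] * (n_classes - rem)
    classes = np.empty(n, dtype=np.int64)
    pos = 0
    for cls, size in enumerate(sizes, start=1):
        classes[order[pos : pos + size]] = cls
        pos += size
    return classes


def plant_occurrence_matrix(
    row_marginals: Sequence[float],
    col_marginals: Sequence[float],
    profile: str,
    strength: float,
    total: float,
    rng: np.random.Generator | None = None,
    round_mode: str = "stochastic",
) -> np.ndarray:
    """Build an occurrence table with a planted deviation from independence.

    Starting from the independence expectation (outer product of the
    marginals times ``total``), the designated cells are multiplied —
    the top-top cell by (1 - strength) for the avoidance profile, the
    intermediate-gene rows at the top miRNA rank by (1 + strength) for the
    Λ profile — and the table renormalized back to ``total``. With
    ``round_mode="stochastic"`` each cell is rounded to an integer by a
    seeded Bernoulli draw on its fractional part (conserving ``total`` in
    expectation, each cell off by at most 1); ``round_mode="none"`` returns
    the real-valued expectation.
    """
    if profile not in _PROFILES:
        raise SyntheticError(f"unknown bias profile {profile!r}")
    if not 0 <= strength <= 1:
        raise SyntheticError("strength must lie in [0, 1]")
    r = np.asarray(row_marginals, dtype=float)
    c = np.asarray(col_marginals, dtype=float)
    r, c = r / r.sum(), c / c.sum()
    table = np.outer(r, c) * float(total)
    if profile in (AVOIDANCE, AVOIDANCE_LAMBDA):
        table[-1, -1] *= 1.0 - strength
    if profile in (LAMBDA, AVOIDANCE_LAMBDA):
        table[1:-1, -1] *= 1.0 + strength
    if table.sum() > 0:
        table *= float(total) / table.sum()
    if round_mode == "none":
        return table
    if round_mode != "stochastic":
        raise SyntheticError(f"unknown round_mode {round_mode!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    floor = np.floor(table)
    frac = table - floor
    return floor + (rng.random(table.shape) < frac)


def sample_planted_occurrences(
    row_marginals: Sequence[float],
    col_marginals: Sequence[float],
    profile: str,
    strength: float,
    total: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson replicate around the planted expectation (for simulations)."""
    expectation = plant_occurrence_matrix(
        row_marginals, col_marginals, profile, strength, total,
        round_mode="none",
    )
    return rng.poisson(expectation).astype(float)


def _expression_table(
    base: np.ndarray,
    ids: Sequence[str],
    organs: Sequence[str],
    organ_sdlog: float,
    zero_inflation: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-organ values around a per-entity base with expression-dependent
    dropout: the mute probability decreases with the entity's overall
    expression (lowly expressed entities drop out more often)."""
    n, k = base.size, len(organs)
    noise = rng.lognormal(mean=0.0, sigma=organ_sdlog, size=(n, k))
    values = base[:, None] * noise
    pct = stats_rankpct(base)
    p_mute = np.clip(2.0 * zero_inflation * (1.0 - pct), 0.0, 0.95)
    mute = rng.random((n, k)) < p_mute[:, None]
    values[mute] = 0.0
    # every entity must be detectable somewhere
    all_zero = ~(values > 0).any(axis=1)
    if all_zero.any():
        cols = rng.integers(0, k, size=int(all_zero.sum()))
        values[np.flatnonzero(all_zero), cols] = base[all_zero]
    return pd.DataFrame(values, index=list(ids), columns=list(organs))


def stats_rankpct(values: np.ndarray) -> np.ndarray:
    """Percentile (0..1) of each value within the array, ties by order."""
    order = np.argsort(values, kind="stable")
    pct = np.empty(values.size)
    pct[order] = np.arange(values.size) / max(values.size - 1, 1)
    return pct


def generate_fixture_set(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate the full fixture bundle and write it to ``out_dir``.

    Writes gene and miRNA-arm expression TSVs, the age table, the
    mature-precursor map, per-gene UTR lengths, hit tables in both
    predictor dialects describing the same planted targeting pairs, and a
    ground-truth JSON with the planted profile and strengths. Returns the
    mapping of logical names to paths. Deterministic under the seed.
    """
    out_dir = Path(out_dir)
    seed = config.seed
    organs = list(config.organs)

    precursors = [f"hsa-mir-{i:04d}" for i in range(config.n_precursors)]
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]

    # ages, correlated with expression through the base draw below
    rng_age = _rng(seed, _STREAM_AGES)
    ages = rng_age.choice(
        [1, 2, 3, 4], size=config.n_precursors, p=list(config.age_mixture)
    )

    rng_mirna = _rng(seed, _STREAM_MIRNA_EXPR)
    mirna_meanlog = config.meanlog + config.age_expression_shift * (4 - ages)
    mirna_base = rng_mirna.lognormal(mean=mirna_meanlog, sigma=config.sdlog)
    mirna_expr = _expression_table(
        mirna_base, precursors, organs, config.organ_sdlog,
        config.zero_inflation, rng_mirna,
    )

    rng_gene = _rng(seed, _STREAM_GENE_EXPR)
    gene_base = rng_gene.lognormal(
        mean=config.meanlog, sigma=config.sdlog, size=config.n_genes
    )
    gene_expr = _expression_table(
        gene_base, genes, organs, config.organ_sdlog,
        config.zero_inflation, rng_gene,
    )

    # feasibility before writing anything
    for organ in organs:
        if (gene_expr[organ] > 0).sum() < 10:
            raise SyntheticError(f"too few expressed genes in {organ}")
        if (mirna_expr[organ] > 0).sum() < 4:
            raise SyntheticError(f"too few expressed miRNAs in {organ}")

    # mature arms: dominant arm carries the precursor count, the minor arm
    # (if present) a random fraction of it
    rng_arms = _rng(seed, _STREAM_ARMS)
    arm_rows = []
    mature_of: dict[str, list[str]] = {}
    for i, prec in enumerate(precursors):
        arms = ["5p", "3p"][: config.n_mature_per_precursor]
        if config.n_mature_per_precursor == 2 and rng_arms.random() < 0.3:
            arms = ["5p"]  # some precursors have a single annotated arm
        mature_of[prec] = [f"{prec}-{arm}" for arm in arms]
        dominant = arms[int(rng_arms.integers(0, len(arms)))]
        for arm in arms:
            frac = 1.0 if arm == dominant else rng_arms.uniform(0.05, 0.6)
            arm_rows.append(
                {"precursor_id": prec, "arm": arm}
                | {z: mirna_expr.loc[prec, z] * frac for z in organs}
            )
    arm_table = pd.DataFrame(arm_rows)

    matures = [m for prec in precursors for m in mature_of[prec]]
    m2h = pd.DataFrame(
        0, index=pd.Index(matures, name="mature_id"),
        columns=pd.Index(precursors, name="precursor_id"), dtype=np.int8,
    )
    for prec, ms in mature_of.items():
        for m in ms:
            m2h.loc[m, prec] = 1

    # planted targeting pairs on cross-organ mean classes
    rng_pairs = _rng(seed, _STREAM_PAIRS)
    gene_classes = _quantile_classes(gene_expr.mean(axis=1).to_numpy(), 11)
    mirna_classes = _quantile_classes(mirna_expr.mean(axis=1).to_numpy(), 5)
    gene_by_class = {
        l: np.flatnonzero(gene_classes == l) for l in range(1, 12)
    }
    pairs: set[tuple[int, int]] = set()
    for t in (1, 2, 3, 4):
        prec_idx = np.flatnonzero(ages == t)
        if prec_idx.size == 0:
            continue
        n_pairs_t = int(round(
            config.n_target_pairs * prec_idx.size / config.n_precursors
        ))
        if n_pairs_t == 0:
            continue
        prec_by_rank = {
            j: prec_idx[mirna_classes[prec_idx] == j] for j in range(1, 6)
        }
        row_m = np.array([len(gene_by_class[l]) for l in range(1, 12)], float)
        col_m = np.array([len(prec_by_rank[j]) for j in range(1, 6)], float)
        if col_m.sum() == 0:
            continue
        strength_t = min(
            1.0, config.strength * config.age_strength[t - 1]
        )
        prob = plant_occurrence_matrix(
            row_m / row_m.sum(), col_m / col_m.sum(),
            config.bias_profile, strength_t, 1.0, round_mode="none",
        )
        prob[row_m == 0, :] = 0.0
        prob[:, col_m == 0] = 0.0
        prob = prob / prob.sum()
        cell_counts = rng_pairs.multinomial(n_pairs_t, prob.ravel()).reshape(11, 5)
        for l in range(1, 12):
            for j in range(1, 6):
                m = int(cell_counts[l - 1, j - 1])
                if m == 0:
                    continue
                gs = rng_pairs.choice(gene_by_class[l], size=m)
                hs = rng_pairs.choice(prec_by_rank[j], size=m)
                pairs.update(zip(gs.tolist(), hs.tolist()))

    # target sites for the sampled pairs, with deliberate overlaps
    rng_sites = _rng(seed, _STREAM_SITES)
    rng_utr = _rng(seed, _STREAM_UTR)
    utr_lengths = pd.Series(
        rng_utr.integers(500, 3000, size=config.n_genes),
        index=genes, name="utr3_length",
    )
    ctx_hits: list[tm.TargetSiteHit] = []
    acc_hits: list[tm.TargetSiteHit] = []

    def add_site(gene: str, mature: str, start: int, eight_mer: bool) -> None:
        length = 8 if eight_mer else 7
        end = start + length - 1
        ctx_hits.append(tm.TargetSiteHit(
            gene, mature, start, end,
            "8mer-1a" if eight_mer else "7mer-m8",
            float(rng_sites.uniform(-1.3, -0.65)),
        ))
        acc_hits.append(tm.TargetSiteHit(
            gene, mature, start, end,
            "8:0:0" if eight_mer else "7:0:0",
            float(rng_sites.uniform(-30.0, -10.0)),
        ))

    for g_idx, h_idx in sorted(pairs):
        gene, prec = genes[g_idx], precursors[h_idx]
        ms = mature_of[prec]
        mature = ms[int(rng_sites.integers(0, len(ms)))]
        limit = int(utr_lengths[gene]) - 10
        start = int(rng_sites.integers(1, limit))
        eight = bool(rng_sites.random() < 0.3)
        add_site(gene, mature, start, eight)
        if rng_sites.random() < config.overlap_rate:
            add_site(gene, mature, start + int(rng_sites.integers(1, 6)), eight)
        if rng_sites.random() < config.extra_site_rate:
            add_site(gene, mature, int(rng_sites.integers(1, limit)),
                     bool(rng_sites.random() < 0.3))

    # write the bundle
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_expression": out_dir / "gene_expression.tsv",
        "mirna_arm_counts": out_dir / "mirna_arm_counts.tsv",
        "ages": out_dir / "ages.tsv",
        "mature_map": out_dir / "mature_map.tsv",
        "utr_lengths": out_dir / "utr_lengths.tsv",
        "hits_context": out_dir / "hits_context.tsv",
        "hits_accessibility": out_dir / "hits_accessibility.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    gene_expr.rename_axis("gene_id").to_csv(paths["gene_expression"], sep="\t")
    arm_table.to_csv(paths["mirna_arm_counts"], sep="\t", index=False)
    pd.DataFrame({"precursor_id": precursors, "t": ages}).to_csv(
        paths["ages"], sep="\t", index=False
    )
    m2h.to_csv(paths["mature_map"], sep="\t")
    utr_lengths.rename_axis("gene_id").to_frame().to_csv(
        paths["utr_lengths"], sep="\t"
    )
    tm.write_hit_table(ctx_hits, paths["hits_context"], tm.CONTEXT_SCORE)
    tm.write_hit_table(acc_hits, paths["hits_accessibility"], tm.ACCESSIBILITY)
    truth = asdict(config) | {
        "n_planted_pairs": len(pairs),
        "n_context_hits": len(ctx_hits),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, default=list))
    return paths
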