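"""End-to-end orchestration: ingest -> matrices -> binning -> bias -> repression.

The pipeline sequences the analysis stages over a structured run
configuration and emits tidy tab-delimited outputs: per-(organ, age) bias
tables, an index table (avoidance A, preference H with components, shape
calls), the age-comparison signed-rank results, the expression-age trend
test, and, when enabled, the repression level-shift matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import bias as bs
from . import binning as bn
from . import repression as rp
from . import target_matrix as tm

logger = logging.getLogger("mirspec")


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage name."""


@dataclass
class RunConfig:
    hits: str
    dialect: str
    mature_map: str
    ages: str
    gene_expression: str
    mirna_arm_counts: str
    organs: tuple[str, ...]
    out_dir: str
    threshold: float | None = None
    named_set: str | None = None
    flank_up: int = 0
    utr_lengths: str | None = None
    brain_subregions: tuple[str, ...] = ()
    brain_name: str = "brain"
    ages_to_analyze: tuple[int, ...] = (1, 2)
    repression: bool = True
    jt_test: bool = True
    pair_mode: str = rp.ALL_PAIRS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("organs", "brain_subregions", "ages_to_analyze"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        if not self.organs:
            raise PipelineError("organ list must be nonempty")
        for name in ("hits", "mature_map", "ages", "gene_expression",
                     "mirna_arm_counts"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise PipelineError(f"config path {name!r} missing: {path}")
        if self.utr_lengths is not None and not Path(self.utr_lengths).exists():
            raise PipelineError(f"utr_lengths path missing: {self.utr_lengths}")
        if self.threshold is None and self.named_set is None:
            raise PipelineError("either threshold or named_set is required")

    def filter_spec(self) -> tm.HitFilterSpec:
        if self.named_set is not None:
            spec = tm.NAMED_FILTER_SETS[self.named_set]
            if spec.dialect != self.dialect:
                raise PipelineError(
                    f"named set {self.named_set} is for dialect {spec.dialect}"
                )
            return spec
        return tm.HitFilterSpec(self.dialect, float(self.threshold))


@dataclass
class RunResult:
    bias_tables: pd.DataFrame
    index_table: pd.DataFrame
    test_results: pd.DataFrame
    delta: rp.DeltaMatrices | None = None
    shift_summary: pd.DataFrame | None = None
    universe_log: dict[str, int] = field(default_factory=dict)


def _canonicalize_organs(
    table: pd.DataFrame, organs: Sequence[str], what: str
) -> pd.DataFrame:
    """Case-insensitive match of table columns onto the configured organ
    list; unmatched columns are an error rather than silently dropped."""
    lookup = {o.lower(): o for o in organs}
    renames = {}
    for col in table.columns:
        if col.lower() not in lookup:
            raise PipelineError(
                f"{what}: organ column {col!r} not in the configured organ list"
            )
        renames[col] = lookup[col.lower()]
    table = table.rename(columns=renames)
    missing = [o for o in organs if o not in table.columns]
    if missing:
        raise PipelineError(f"{what}: organs missing from table: {missing}")
    return table[list(organs)]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and rethrow
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return inner
    return wrap


@_stage("ingest")
def _ingest(config: RunConfig) -> pd.DataFrame:
    spec = config.filter_spec()
    if config.dialect == tm.CONTEXT_SCORE:
        hits = tm.read_context_hits(config.hits)
        utr = None
    else:
        hits = tm.read_accessibility_hits(config.hits, flank_up=config.flank_up)
        utr = None
        if config.utr_lengths is not None:
            lengths = pd.read_csv(config.utr_lengths, sep="\t", index_col=0)
            utr = lengths.iloc[:, 0].to_dict()
    kept = tm.filter_hits(hits, spec, utr)
    dedup = tm.deduplicate_hits(kept)
    logger.info(
        "ingest: %d hits read, %d after score filter, %d nonredundant",
        len(hits), len(kept), len(dedup),
    )
    m2h = tm.read_matrix(config.mature_map)
    matures = list(m2h.index.astype(str))
    unknown = sorted({h.mature_id for h in dedup} - set(matures))
    if unknown:
        raise PipelineError(f"hits reference unmapped matures: {unknown[:5]}")
    g2m = tm.build_gene_to_mature(dedup, matures=matures)
    return tm.compose_gene_to_precursor(g2m, m2h)


@_stage("expression")
def _expression(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    arm_counts = bn.read_arm_counts(config.mirna_arm_counts)
    mirna_expr = bn.collapse_arm_counts(arm_counts)
    gene_expr = bn.read_expression_table(config.gene_expression)
    if config.brain_subregions:
        for name, table in (("miRNA", mirna_expr), ("gene", gene_expr)):
            present = [s for s in config.brain_subregions if s in table.columns]
            if present:
                merged = bn.aggregate_brain_subregions(
                    table, config.brain_subregions, config.brain_name
                )
                if name == "miRNA":
                    mirna_expr = merged
                else:
                    gene_expr = merged
    mirna_expr = _canonicalize_organs(mirna_expr, config.organs, "miRNA table")
    gene_expr = _canonicalize_organs(gene_expr, config.organs, "gene table")
    ages = bn.read_age_table(config.ages)
    return gene_expr, mirna_expr, ages


@_stage("binning")
def _binning(
    g2h: pd.DataFrame,
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    ages: pd.Series,
    universe_log: dict[str, int],
) -> tuple[pd.DataFrame, bn.RankTable, bn.RankTable, pd.DataFrame, pd.Series]:
    genes_in = gene_expr.index.intersection(g2h.index)
    precs_in = mirna_expr.index.intersection(g2h.columns).intersection(ages.index)
    gene_expr = bn.drop_unexpressed(gene_expr.loc[genes_in])
    mirna_expr = bn.drop_unexpressed(mirna_expr.loc[precs_in])
    universe_log.update(
        genes_total=len(g2h.index),
        genes_used=len(gene_expr),
        genes_dropped=len(g2h.index) - len(gene_expr),
        precursors_total=len(g2h.columns),
        precursors_used=len(mirna_expr),
        precursors_dropped=len(g2h.columns) - len(mirna_expr),
    )
    logger.info("universes: %s", universe_log)
    g2h = g2h.loc[gene_expr.index, mirna_expr.index]
    gene_levels = bn.assign_ranks(gene_expr, n_bins=11)
    mirna_ranks = bn.assign_ranks(mirna_expr, n_bins=5)
    return g2h, gene_levels, mirna_ranks, gene_expr, ages


@_stage("bias")
def _bias(
    g2h: pd.DataFrame,
    gene_levels: bn.RankTable,
    mirna_ranks: bn.RankTable,
    ages: pd.Series,
    organs: Sequence[str],
    ages_to_analyze: Sequence[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    bias_rows, index_rows = [], []
    for organ in organs:
        for age in ages_to_analyze:
            o11 = bs.count_occurrences(
                g2h, gene_levels.column(organ), mirna_ranks.column(organ),
                ages, age, organ=organ,
            )
            if o11.counts.sum() == 0:
                index_rows.append(
                    {"organ": organ, "age": age, "A": np.nan,
                     "A_status": bs.NOT_AVAILABLE, "shape": bs.NEITHER,
                     "H": np.nan, "H_rise": np.nan, "H_dive": np.nan,
                     "H_status": bs.NOT_AVAILABLE}
                )
                continue
            o5 = bs.convert_levels_to_ranks(o11)
            e5 = bs.expected_counts(o5)
            b5 = bs.signed_bias(o5, e5)
            bias_rows.append(bs.bias_frame(o5, e5, b5))
            a = bs.avoidance_index(b5)
            top_ok = np.isfinite(b5.bias[:, 4]).all()
            shape = bs.shape_call(b5.bias[:, 4]) if top_ok else bs.NEITHER
            h = (
                bs.preference_index(b5.bias[:, 4], b5.chi2[:, 4])
                if top_ok
                else bs.IndexValue(status=bs.NOT_AVAILABLE)
            )
            index_rows.append(
                {
                    "organ": organ,
                    "age": age,
                    "A": a.value if a.defined else np.nan,
                    "A_status": a.status or "",
                    "shape": shape,
                    "H": h.value if h.defined else np.nan,
                    "H_rise": h.components.get("H_rise", np.nan),
                    "H_dive": h.components.get("H_dive", np.nan),
                    "H_status": h.status or "",
                }
            )
    bias_tables = (
        pd.concat(bias_rows, ignore_index=True) if bias_rows else pd.DataFrame()
    )
    return bias_tables, pd.DataFrame(index_rows)


def _index_series(index_table: pd.DataFrame, column: str, age: int,
                  organs: Sequence[str]) -> list[float | None]:
    sub = index_table[index_table["age"] == age].set_index("organ")
    out: list[float | None] = []
    for organ in organs:
        if organ not in sub.index:
            out.append(None)
            continue
        v = sub.loc[organ, column]
        out.append(None if pd.isna(v) else float(v))
    return out


@_stage("tests")
def _tests(
    index_table: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    ages: pd.Series,
    organs: Sequence[str],
    ages_to_analyze: Sequence[int],
    jt_test: bool,
) -> pd.DataFrame:
    rows = []
    if len(ages_to_analyze) >= 2:
        t1, t2 = ages_to_analyze[0], ages_to_analyze[1]
        for column in ("A", "H"):
            res = bs.paired_signed_rank_test(
                _index_series(index_table, column, t1, organs),
                _index_series(index_table, column, t2, organs),
            )
            rows.append(
                {"test": f"signed_rank_{column}", "ages": f"{t1}v{t2}",
                 "statistic": res.statistic, "p": res.p, "n": res.n,
                 "status": res.status or ""}
            )
    if jt_test:
        # each miRNA-organ expression value is one observation, grouped by
        # age class ordered youngest -> oldest so the stated trend (older
        # miRNAs more highly expressed) is the increasing alternative
        groups = []
        for t in (4, 3, 2, 1):
            members = ages.index[ages == t].intersection(mirna_expr.index)
            values = mirna_expr.loc[members].to_numpy().ravel()
            if values.size:
                groups.append(values)
        if len(groups) >= 2:
            res = bs.jonckheere_terpstra_test(groups, alternative="increasing")
            rows.append(
                {"test": "jonckheere_terpstra", "ages": "4..1",
                 "statistic": res.statistic, "p": res.p, "n": res.n,
                 "status": res.status or ""}
            )
    return pd.DataFrame(rows)


@_stage("repression")
def _repression(
    g2h: pd.DataFrame,
    gene_expr: pd.DataFrame,
    mirna_ranks: bn.RankTable,
    pair_mode: str,
) -> tuple[rp.DeltaMatrices, pd.DataFrame]:
    cross = bn.assign_cross_organ_levels(gene_expr)
    eligible = rp.find_alpha_beta_mirnas(mirna_ranks)
    logger.info("repression: %d eligible miRNAs", len(eligible))
    targeted = rp.build_pair_multiset(eligible, g2h, cross, True, pair_mode)
    background = rp.build_pair_multiset(eligible, g2h, cross, False, pair_mode)
    delta = rp.normalize_and_ratio(targeted, background)
    rows = []
    for alpha in range(1, 12):
        summary = rp.shift_fractions(delta.delta[alpha - 1], alpha)
        rows.append(
            {"alpha_level": alpha, "frac_down": summary.frac_down,
             "frac_same": summary.frac_same, "frac_up": summary.frac_up,
             "n": summary.n, "status": summary.status or ""}
        )
    return delta, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run all stages and write tab-delimited outputs to ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    universe_log: dict[str, int] = {}

    g2h = _ingest(config)
    gene_expr, mirna_expr, ages = _expression(config)
    g2h, gene_levels, mirna_ranks, gene_expr, ages = _binning(
        g2h, gene_expr, mirna_expr, ages, universe_log
    )
    bias_tables, index_table = _bias(
        g2h, gene_levels, mirna_ranks, ages, config.organs,
        config.ages_to_analyze,
    )
    # the trend test uses the expression values of the binned universe
    mirna_expr_used = mirna_expr.loc[mirna_ranks.ranks.index]
    test_results = _tests(
        index_table, mirna_expr_used, ages, config.organs,
        config.ages_to_analyze, config.jt_test,
    )

    delta = shift_summary = None
    if config.repression:
        delta, shift_summary = _repression(
            g2h, gene_expr, mirna_ranks, config.pair_mode
        )

    bias_tables.to_csv(out_dir / "bias_tables.tsv", sep="\t", index=False)
    index_table.to_csv(out_dir / "index_table.tsv", sep="\t", index=False)
    test_results.to_csv(out_dir / "test_results.tsv", sep="\t", index=False)
    if delta is not None:
        rp.matrix_frame(delta.delta).to_csv(out_dir / "delta.tsv", sep="\t")
        rp.matrix_frame(delta.delta_rownorm).to_csv(
            out_dir / "delta_rownorm.tsv", sep="\t"
        )
        rp.matrix_frame(delta.background).to_csv(
            out_dir / "delta_background.tsv", sep="\t"
        )
        rp.matrix_frame(delta.ratio).to_csv(out_dir / "ratio_k.tsv", sep="\t")
        shift_summary.to_csv(out_dir / "shift_summary.tsv", sep="\t", index=False)
    (out_dir / "universe_log.tsv").write_text(
        "key\tvalue\n"
        + "".join(f"{k}\t{v}\n" for k, v in universe_log.items())
    )
    return RunResult(
        bias_tables=bias_tables,
        index_table=index_table,
        test_results=test_results,
        delta=delta,
        shift_summary=shift_summary,
        universe_log=universe_log,
    )


def _fmt_value(v, status: str) -> str:
    if status or pd.isna(v):
        return "-"
    return f"{v:.3g}"


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "-"
    return f"{p:.1g}"


def table1_report(
    index_table: pd.DataFrame,
    ages: Sequence[int] = (1, 2),
    organs: Sequence[str] | None = None,
) -> str:
    """Render the index table as a report: organs as columns, rows for the
    avoidance index, shape call and preference index per age, with the
    paired signed-rank p (recomputed from the table's values, one
    significant figure) in the last column. Undefined entries print "-"."""
    if organs is None:
        organs = list(dict.fromkeys(index_table["organ"]))
    if len(ages) < 2:
        p_a = p_h = None
    else:
        p_a = bs.paired_signed_rank_test(
            _index_series(index_table, "A", ages[0], organs),
            _index_series(index_table, "A", ages[1], organs),
        ).p
        p_h = bs.paired_signed_rank_test(
            _index_series(index_table, "H", ages[0], organs),
            _index_series(index_table, "H", ages[1], organs),
        ).p
    by_age = {
        age: index_table[index_table["age"] == age].set_index("organ")
        for age in ages
    }

    def row(label: str, age: int, column: str, p: str) -> list[str]:
        cells = []
        sub = by_age[age]
        for organ in organs:
            if organ not in sub.index:
                cells.append("-")
            elif column == "shape":
                cells.append(
                    "L" if sub.loc[organ, "shape"] == bs.LAMBDA else "-"
                )
            else:
                status = sub.loc[organ, f"{column}_status"]
                cells.append(_fmt_value(sub.loc[organ, column], status))
        return [label, f"age {age}"] + cells + [p]

    header = ["indicator", "origin"] + list(organs) + ["p"]
    lines = []
    for label, column, p in (
        ("avoid_index_A", "A", _fmt_p(p_a)),
        ("prefer_shape", "shape", ""),
        ("prefer_index_H", "H", _fmt_p(p_h)),
    ):
        for i, age in enumerate(ages):
            lines.append(row(label, age, column, p if i == 0 else ""))
    widths = [
        max(len(str(r[i])) for r in [header] + lines)
        for i in range(len(header))
    ]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    return "\n".join(fmt.format(*r) for r in [header] + lines)
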