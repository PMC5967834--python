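# mirspec

Quantifying miRNA targeting specificity from predicted target sites and
by-organ expression profiles.

## What it does, and for whom

MicroRNAs repress mRNAs through short seed matches, so highly expressed
miRNAs exert pressure on every co-expressed gene carrying a site. Genes
can evolve to avoid such sites; targeting may also be preferentially
retained at particular expression regimes. `mirspec` is for
computational biologists who have (a) predicted target-site tables (two
dialects supported: context-score and accessibility/ΔΔG scoring) and
(b) expression tables of miRNA precursors and protein-coding genes across
organs, plus an age (time-of-origin) class per miRNA, and who want to ask:
*at which combinations of miRNA and target expression is targeting
over- or under-represented, and does that specificity differ between
miRNA age classes?*

## The statistics at its core

Targeting occurrences — (gene, precursor) pairs with at least one
predicted site — are cross-tabulated per organ z and miRNA age class t by
gene expression level i (five ranks, smoothed from eleven levels) and
miRNA expression rank j (five ranks; rank 1 = mute in that organ). With
E<sub>ij</sub> the independence expectation from the table's marginals and
C<sub>ij</sub> = (O<sub>ij</sub> − E<sub>ij</sub>)²/E<sub>ij</sub> the
Pearson cell statistic, each cell's signed bias is

> B<sub>ijzt</sub> = −log₁₀ P(X > C<sub>ijzt</sub>), X ~ χ²₁, signed
> positive when O ≥ E and negative otherwise.

From the top miRNA rank's column the pipeline derives the **avoidance
index** A = C₅₅ + C₅₁ (defined when B₅₁ > 0 and B₅₅ < 0, otherwise "not
in order"), the **Λ-shape criterion** (inner gene ranks all above both
outer ones), and the **preference index** H = H_rise + H_dive (the Λ
height). Indices of two age classes are compared per organ with an exact
two-sided Wilcoxon signed-rank test under a pseudo-0 rule for one-sided
"not in order" entries, and the expression–age trend is assessed with a
Jonckheere–Terpstra test. A separate repression analysis follows genes of
miRNAs that are mute in one organ (α) and top-expressed in another (β)
through 11×11 level-shift matrices δ, δ′, a background from untargeted
genes, and their ratio K. See `docs/methods.md` for the full model.

## Worked example

Per-organ avoidance indices for the two oldest miRNA age classes from a
genome-wide analysis ship with the package; comparing them takes three
lines:

```python
from mirspec import paired_signed_rank_test
from mirspec import example_data as ex

res = paired_signed_rank_test(ex.AVOIDANCE_ANTE, ex.AVOIDANCE_EUTH)
print(res.n, res.p)        # 9 0.00390625
res = paired_signed_rank_test(ex.PREFERENCE_ANTE, ex.PREFERENCE_EUTH)
print(res.n, res.p)        # 9 0.01171875
```

Nine organ pairs are usable for the avoidance comparison (one organ is
out of order on both sides and is excluded); every difference favors the
older class, so the exact two-sided p is 2/2⁹ = 0.0039 (printed 0.004 at
one significant figure). The preference comparison has one discordant
organ of low rank, giving p = 6/2⁹ ≈ 0.0117 (printed 0.01).

A complete run on synthetic data with planted avoidance + Λ preference:

```sh
mirspec generate --out-dir fixtures --seed 3 \
  --config <(echo '{bias_profile: avoidance_lambda, strength: 0.7}')
mirspec run-all --config run.yaml   # paths to the generated files
```

prints the index report (ages 1 = oldest, 2 = next):

```
indicator       origin  brain  heart  kidney  liver  ovary  testis  p
avoid_index_A   age 1   8.91   24.3   20.9    16.3   14     10.6    0.03
avoid_index_A   age 2   6.48   4.49   -       4.69   5.12   -
prefer_shape    age 1   -      -      -       L      L      -
prefer_shape    age 2   -      -      -       -      -      -
prefer_index_H  age 1   -      -      -       -      2.67   -       1
prefer_index_H  age 2   -      -      -       -      -      -
```

The planted avoidance is recovered in every organ and is stronger for the
older class (signed-rank p = 0.03 across six organs); "-" marks "not in
order" or unavailable entries. Full tidy tables (per-cell bias tables,
index table, test results, repression matrices) are written to the run's
output directory as TSV.

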