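# Methods

## The question the pipeline answers

MicroRNAs (miRNAs) repress mRNAs through ~7-nt seed complementarity, so a
miRNA that is highly expressed in an organ exerts pressure on every
co-expressed gene carrying a matching 3′-UTR site. Genes under that
pressure can evolve to lose sites (selective avoidance); conversely,
targeting may be preferentially retained at particular expression regimes.
`mirspec` quantifies both directions from two observable layers: predicted
target sites (a proxy for targeting) and by-organ expression profiles of
miRNAs and protein-coding genes. Targeting occurrences are stratified by
the expression rank of the miRNA, the expression level of the gene, the
organ, and the evolutionary age class of the miRNA, and each stratum's
deviation from independence is scored.

## Targeting matrices

Predicted sites arrive as tab-delimited hit tables in either of two
dialects (context-score or accessibility scoring; more negative = stronger
in both). Processing:

1. keep only exact 7-mer/8-mer seed classes and scores strictly below the
   configured threshold; in the accessibility dialect the whole site must
   lie inside the 3′ UTR (flank overhangs are dropped);
2. collapse overlapping sites per (gene, mature miRNA): scanning 5′→3′, a
   site overlapping an already retained one is removed, so chains keep
   their outer sites and stacks keep only the most-5′ site;
3. count sites into `g2m` (genes × matures), map matures to precursor
   hairpins with the binary `m2h`, and form the binary
   `G2H = 1(g2m · m2h > 0)`. Multiple sites still mark a single (gene,
   precursor) pair; a mature shared by several precursors marks all of
   them.

Score thresholds are configuration values. The named context-score sets
C010/C020/C030 default to −0.4/−0.5/−0.6 (two threshold conventions exist
in circulation for these set names — −0.1/−0.2/−0.3 is the other — and the
package deliberately exposes the choice rather than hard-coding one). The
accessibility sets P010/P020/P030 (−0.96/−3.69/−9.49) were calibrated so
each matches the hit count of its context-score counterpart;
`calibrate_threshold` reproduces that calibration for new data, resolving
ties toward the stricter count.

Tie rules the site data do not determine are fixed deterministically:
equal-start overlapping sites keep the longer site; the representative
transcript of a gene is chosen by longest CDS, most-downstream coding end,
longest 3′ UTR, longest transcript, then smallest transcript id.

## Expression binning

Precursor abundances take the larger of the 3p/5p arm counts; brain
sub-region columns (e.g. frontal cortex, midbrain, hippocampus) are
averaged into one brain column. Entities with zero abundance in every
organ are dropped from the universe. Within each organ, rank 1 / level I
holds exactly the *mute* entities (zero here, detectable elsewhere); the
remaining entities are sorted by (value, id) and cut into equally
populated bins — 4 upper bins for the five-rank miRNA scale, 10 for the
eleven-level gene scale — with remainders assigned to the lowest bins
first. Ranks are therefore scale-invariant and deterministic; ties may
straddle bin boundaries. The repression analysis instead bins all
(gene, organ) values on one global eleven-level scale so levels are
comparable between organs.

## Bias, indices, shape

For organ z and age class t, `o[l, j]` counts pairs with `G2H = 1`, gene
level l (1–11) and miRNA rank j (1–5). The 11-level rows are smoothed to
five gene ranks (level I → rank 1; means of II–IV, V–VII, VIII–X → ranks
2–4; XI → rank 5), giving `O[i, j]`. With W the grand total,
`E = (row sum)(col sum)/W`, the cell statistic is `C = (O − E)²/E`, and

    B = −log10 P(X > C),  X ~ χ²(ν = 1),   signed + if O ≥ E, − otherwise.

The chi-square machinery is applied to the averaged (real-valued) counts
as-is; no continuity correction. Tail probabilities are floored at 1e-300
(bias capped at ±300) and such cells flagged; cells with E = 0 < O are
flagged not-available.

From the five-rank table:

* avoidance `A = C[5,5] + C[5,1]` when `B[5,1] > 0` and `B[5,5] < 0`,
  otherwise "not in order";
* the Λ criterion on the top-miRNA column: Λ when
  `min(B[2..4,5]) > max(B[1,5], B[5,5])`, V for the mirror, else neither;
* preference `H = H_rise + H_dive` with `H_rise` the C at the argmax of
  the inner biases and `H_dive` the C at the larger outer bias, defined
  when the best inner bias is positive and both outer biases negative.
  Argmax ties resolve to the smaller gene rank.

## Tests

**Age comparison.** Indices of two age classes are paired per organ.
"Not in order" on one side scores the pseudo value 0; organs undefined on
both sides are excluded. The two-sided Wilcoxon signed-rank test is then
exact: zero differences dropped, tied magnitudes mid-ranked, and the null
distribution of the rank sum computed by dynamic programming over doubled
mid-ranks — equivalent to enumerating all 2^n sign assignments — for
n ≤ 25, with a tie-corrected normal approximation beyond.

**Expression–age trend.** The Jonckheere–Terpstra statistic sums
Mann–Whitney counts over ordered group pairs (ties half-weighted). The
permutation null is enumerated exactly when the number of distinct group
assignments is at most 2×10⁵, otherwise approximated normally with tie
correction. The pipeline pools each miRNA–organ expression value as one
observation, groups by age class ordered youngest → oldest, and tests the
one-sided increasing alternative (older ⇒ higher expression); grouping and
sidedness are an interpretation and are overridable.

## Repression level shifts

A miRNA is *eligible* when it is mute (rank 1, the α condition) in at
least one organ and top-ranked (rank 5, the β condition) in another. For
each eligible miRNA and each targeted gene, every (α organ, β organ)
combination contributes one ordered tuple of the gene's cross-organ
levels, accumulated into the 11×11 matrix δ; the existential quantifier in
the tuple definition is ambiguous about multiplicity, so the all-pairs
reading (matching the multiset formalism) is the default and a canonical
single-pair mode (first α organ, first β organ in column order) is the
config alternative. Untargeted genes of the same eligible miRNAs give the
background δ̄. Outputs are the row-normalized δ′ and δ̄′, the ratio
`K = (δ/Σδ)/(δ̄/Σδ̄)` (undefined where the background cell is empty), and
per-row fractions of mass below/at/above the α level (DSuβ / same / USuβ).
Fractions are compared with a two-sided pooled-variance two-proportion
test, falling back to Fisher's exact test when any pooled expected cell is
below 5; this comparison is the package's own choice of test.

## Synthetic data

The generator emulates the structure the analysis assumes:

* log-normal expression (defaults meanlog 2.0, sdlog 2.0 on the natural
  log scale, per-organ multiplicative noise sdlog 0.5) with per-organ
  dropout averaging `zero_inflation = 0.25`; dropout probability decreases
  with an entity's overall expression, so an organ's mute set is enriched
  for genuinely low-expression entities, as in clone-count data;
* four age classes with mixture (0.30, 0.25, 0.25, 0.20) and meanlog
  increment 0.8 per step of age, making older miRNAs more highly
  expressed;
* precursors with one or two mature arms (dominant arm carries the
  count), six organs, 600 genes × 150 precursors, ~6000 targeting pairs
  by default — sizes chosen so a full run takes about a second while every
  stratum stays populated;
* targeting pairs sampled from a planted (gene level × miRNA rank)
  distribution: starting from the independence outer product, the top-top
  cell is multiplied by (1 − strength) for the avoidance profile and the
  intermediate-gene rows at the top miRNA rank by (1 + strength) for the
  Λ profile, renormalized to the requested total. Per-age multipliers
  (default 1.0/0.5/0.25/0.25) make the planted signal stronger for older
  classes. Depleting only the top-top cell suffices to produce the
  positive mute-column bias the avoidance index requires, because the
  depleted table's own marginals define the expectation;
* sites for sampled pairs get uniform coordinates within per-gene UTR
  lengths, with overlapping extra sites injected at rate 0.15 to exercise
  overlap removal, written in both dialects over the same coordinates.

`plant_occurrence_matrix` rounds cells stochastically (each off by at most
1, total conserved in expectation); `sample_planted_occurrences` draws
Poisson replicates around the planted expectation for simulations. A
single seed drives everything through fixed per-purpose substreams, so
outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: sequence-level seed matching and
thermodynamics, clone-count overdispersion beyond zero inflation,
correlated gene modules, and genome-scale universe sizes. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted effects at moderate scale, not the magnitudes any particular real
dataset would produce.

## Numerical and degenerate-input choices

* Tail floor 1e-300 / bias cap 300 keep log-scale biases finite; capped
  cells are flagged rather than silently truncated.
* An organ where every universe entity is mute yields all rank 1; fewer
  nonzero entities than upper bins is an error.
* Empty occurrence tables are an error for the expectation step; the
  pipeline records such (organ, age) strata as not-available instead of
  failing the run.
* Threshold calibration with an empty candidate set warns and returns an
  effectively −∞ threshold.
* All tie-breaks (binning order, overlap removal, argmax, transcript
  choice) are total orders, making every pipeline output deterministic;
  two runs on identical inputs are byte-identical.

## Problem sizes used by the test suite and acceptance script

Simulations use 5×5 tables with totals of 10⁴ (100 replicates per
condition), synthetic bundles of 600×150 entities with ~6000 planted
pairs, and exact-test oracle checks at n ≤ 12 (2^n enumeration) — sizes at
which the planted effects are comfortably identifiable and a full run of
everything completes in well under a minute.

## Known limitations

* Reproducing published genome-scale magnitudes requires the external
  expression atlases and predictor runs those analyses used; this package
  reproduces the procedures and validates them on synthetic data, and
  accepts real data of the documented shapes.
* The choice of test behind the shift-fraction comparison, the trend-test
  grouping, and the existential-quantifier multiplicity are documented
  package choices where the underlying procedure is underdetermined.
* Chi-square tail probabilities on sparsely populated cells (small E) are
  anti-conservative, as the calibration property test shows; interpret
  per-cell biases at small W with care.
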