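# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Input model

Every analysis consumes per-contrast differential-expression tables with
four fields per gene: a unique id, base mean expression (mean normalized
read count, ≥ 0), log2 fold-change (case vs reference), and an
*unadjusted* p-value in (0, 1].  The package is deliberately agnostic to
the DE engine that produced them; rows with missing or invalid p/LFC are
dropped with a logged count, p = 0 rows are rejected rather than silently
kept (a p of exactly zero is not a valid test result and would break the
−log10 ranking).

## DEG criteria

A DEG satisfies p < 0.05, |LFC| > 0.3785 and base mean > 2, all strict
inequalities, optionally restricted to protein-coding genes via an
annotation table.  The LFC default 0.3785 is the value that corresponds
exactly to a 30% fold-change (2^0.3785 − 1 = 0.3001); the near-miss
variant 0.3875 (a 30.8% fold-change) circulates for the same filter and
is accepted through configuration everywhere the cutoff appears.  The
uncorrected-p criterion is intended for broad pattern identification
(heatmaps, Venn overlaps, enrichment inputs), not for per-gene claims.

Percent overlap between DEG sets has two circulating definitions; both
are emitted (`pct_of_union` = 100·|∩|/|∪| and `pct_of_smaller` =
100·|∩|/min(|A|,|B|)) so the reader can use either.

Union LFC matrices take the union of DEG sets as rows and each contrast's
LFC regardless of significance as entries; a union gene absent from a
contrast is a hard error rather than an imputed 0, because a fabricated
fold-change would silently distort clustering.  Rows are clustered by
1 − Pearson correlation with average linkage (UPGMA); rows are
canonicalized to lexicographic id order before agglomeration so that leaf
order is deterministic and invariant to input order, and zero-variance
rows (Pearson undefined) are an error listing the offending genes.

## Primed genes

A gene is primed when the two-hit group differs from standard-control
(p < 0.05 *and* |LFC| above the fold-change cutoff) and from each
single-stress group (p < 0.05 only, either direction, no fold-change
requirement).  The single-stress legs are direction-free on purpose: the
pattern of interest is "the two-hit response is distinct from both
single-hit responses", not "larger than".  Direction is assigned from the
vs-standard-control LFC.  The base-mean filter is inherited from the DE
universe rather than re-applied inside the priming filter.  All three
contrasts must share a gene universe; a mismatch reports the symmetric
difference rather than silently intersecting, since a silently shrunk
universe changes every downstream count.

## Two-sided RRHO

Lists are ranked by s = −log10(p)·sign(LFC) after removing genes with
base mean ≤ 2 (low-expression ranks are dominated by noise).  Equal
scores break by ascending gene id for determinism.  Each list splits at
s = 0; the four sublist pairings form the co-up, co-down, up-down and
down-up quadrants.  For thresholds (i·step, j·step) the observed overlap
k is tested by the hypergeometric tail P(X ≥ k) with the *shared
universe* size N (not the sublist sizes) as the population — this keeps
pixel p-values comparable across quadrants.  Pixel values are
sign·(−log10 p), positive in concordant quadrants, capped at 320 to avoid
floating-point infinities.

Numerical/default choices: step defaults to max(1, N//100), giving on the
order of a 100×100 assembled map; a sublist shorter than one step yields
an empty quadrant with a warning rather than an error (a heavily
one-sided comparison is legitimate data).

Difference maps operate on congruent grids (same universe, step,
dimensions).  Each pixel's 2×2 table is (overlap, A-only, B-only,
neither); log odds ratios use the Haldane–Anscombe +0.5 on all four cells
when any cell is zero; SE = √(Σ 1/cell); Z = (logOR₁ − logOR₂)/√(SE₁² +
SE₂²); two-sided normal p; Benjamini–Hochberg across every pixel of the
map (Bonferroni selectable).  BH was chosen because the pixel grid is
strongly positively dependent (nested overlaps), where BH is conservative
but far less punishing than Bonferroni.

## Cell-type marker enrichment

A gene is a marker of cell type t when its mean expression in t strictly
exceeds 10× the mean of the remaining cell types jointly (the joint-mean
reading, not a pairwise-each-type requirement).  Enrichment of a DEG list
in a marker list is the odds ratio of the 2×2 overlap table within a
user-supplied universe — by default the genes passing the base-mean
filter of the region's DE analysis — with Fisher's exact test, one-tailed
"greater" by default (enrichment semantics), two-sided by flag, and BH
adjustment across the DEG-set × cell-type matrix.

## Signature matching

M = Σ logFC over signature-up genes − Σ over signature-down genes.
Signature genes absent from a profile contribute 0 rather than triggering
rescaling, because profiles are expected to have been reduced to the
expressed, mapped transcriptome upstream.  The permutation null shuffles
the profile's label-to-value assignment (equivalently, the signature's
slots draw values from the profile without replacement) within the
expressed universe; n = 10,000 by default, minimum 100.

The empirical p uses the add-one rule on |M| (two-sided by default —
both mimicking and opposing profiles are of interest; one-sided by flag).
When fewer than 10 permutations reach |M|, the empirical p saturates near
its 1/(n+1) floor, so a generalized Pareto distribution is fitted by
maximum likelihood to the 250 largest |M_perm| above a threshold at the
midpoint of the 250th/251st order statistics; the tail size shrinks in
steps of 10 while a Kolmogorov–Smirnov goodness-of-fit check rejects at
α = 0.05; p = (n_exc/n)·GPD-sf(|M| − threshold).  Degenerate tails fall
back to the empirical p with a flag.  Note the log of a GPD estimate
extrapolated to p ≈ 1e−4 from a 10,000-draw null has a standard deviation
near ln 3 even when the estimator is correct; accuracy checks therefore
aggregate over a panel of seeded nulls rather than judging one draw.

The normalized score (M − mean M_perm)/sd(M_perm) (sample sd, divisor
n − 1) is the permutation z-score used as the effect size; it is what a
battery of profiles is ranked by.  FDR across a battery is BH; the
battery boundary (which profiles are adjusted together) is the caller's
choice.  Per-profile permutation seeds are spawned deterministically from
the battery seed.

## Composite behavior score

Derived measures: sucrose preference = 100·sucrose/(sucrose + water);
NSF ratio = novel-arena latency / home-cage latency.  Outliers are
removed per measure per group in a single pass: |x − group mean| > 2·SD
with statistics including the candidate.  A consequence worth knowing:
the largest attainable deviation under this rule is (n−1)/√n SDs, so no
exclusion can ever occur in groups of four or fewer — the rule is meant
for cohorts of ten or more.  No iteration is performed (iterated trimming
would change the group statistics the rule is defined on).

Each remaining measure is scored against its criterion — mean ± 1 SD of
the reference group (Std-Ctl) in the depression-like direction, or a
fixed constant (sucrose < 50%) — and the composite is 100 × criteria met
/ tests available.  Missing measures reduce the denominator, so cohorts
that omit a test (e.g. no forced swim) remain comparable.

## Synthetic-data generator

The generator emulates the 2×2 design with five gene classes: null (80%),
ELS-persistent (5%, shifted in both ELS groups), stress-responsive (5%,
shifted in both adult-stress groups), primed (5%, shifted only in
ELS-Stress) and primed-opposite (5%, shifted −δ only in ELS-Stress).
Defaults: 5,000 genes, 6 samples/group, δ = 1.0 log2 units, residual
σ = 0.5, baseline log2 abundance Normal(5, 2) — a typical bulk RNA-seq
effect-to-noise regime at a modest cohort size, under which the priming
filter is expected to be sensitive but not saturated.  Expression is
normal on the log2 scale and the internal DE engine is a Welch t-test;
downstream modules consume only (lfc, p, base mean), so the count model
is pluggable (a negative-binomial count emitter is included for
interoperability but not used by the analyses).

Ranked-list pairs for RRHO draw latent effects from a bivariate normal
with correlation ρ (sd 0.5), observed with Normal(0, 0.25) noise and
converted to p via the implied z statistic.  Signature profiles are
±concordance on the signature genes plus Normal(0, 0.2) noise, with pure
noise background genes.  Behavioral cohorts default to 12 mice/group with
1.5-SD planted shifts on three of the four measures in the ELS-Stress
group.

What the generator does *not* emulate — and therefore what passing tests
cannot show about real data: negative-binomial count noise and
mean-dispersion coupling, library-size and batch effects, correlated
genes (co-expression modules), litter effects and sample pooling, sex
differences, and non-normal behavioral distributions.  Recovery rates
measured here characterize the algorithms under clean assumptions, not
expected field performance.

Problem sizes in the test suite and acceptance script (5,000-gene
cohorts, 2,000-gene ranked pairs, 100-replicate batteries at 2,000
permutations, 200 behavioral cohorts, 500-replicate calibration) were
chosen to make every stochastic check stable across seeds while keeping a
full run in tens of seconds.

## Known limitations

* RRHO universe and RPKM: the original RRHO filter is stated in RPKM
  units while the DEG filter uses base mean counts; the module exposes a
  single configurable `min_base_mean` and performs no unit conversion.
* The difference map's multiplicity correction method across pixels is a
  package choice (BH default); published maps may have used another rule.
* GPD p-values far beyond the null support (negative fitted shape,
  observation past the endpoint) underflow to the smallest positive
  float; interpret them as "beyond estimable resolution", not as literal
  probabilities.
* `simple_de` is a stand-in DE engine for synthetic log2-normal data and
  is not appropriate for real count data.
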