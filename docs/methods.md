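# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not establish about real data.

## The data and the two analysis paths

A NanoString nCounter lane yields an integer count per probe. Probe classes:
endogenous targets (default panel size 102), housekeeping references (5),
six positive spike-ins at 128, 32, 8, 2, 0.5, 0.128 fM (the standard ladder
endpoints with 4-fold interior steps; the last step is therefore ~3.9-fold),
and eight negative controls measuring non-specific background.

Two analyses run from the same raw counts and deliberately share no
post-processing state:

1. the **univariate path** (full normalization, then per-gene two-group
   tests), and
2. the **TSP path** (background correction only, then the rank-based pair
   classifier).

The separation is principled: the pair classifier depends only on
within-sample orderings, so positive-control and content scalings — which
are per-lane monotone maps — cannot change any of its outputs. Running it
on minimally processed counts removes the normalization's tuning decisions
from the classifier entirely. A property test applies random strictly
increasing per-sample transforms and checks that no score, search result or
classification moves.

## Lane QC

A lane passes iff binding density ∈ [0.05, 2.25] spots/µm² (inclusive) and
FOV counted/attempted ≥ 0.75. Lanes with missing metadata are flagged
*unevaluable* and excluded rather than silently passed. The FOV criterion
is sometimes quoted as a raw count over 280 attempted frames; the threshold
parameter accepts any ratio, so both readings are expressible
(`min_fov_ratio=75/280` gives the literal low bar).

## Normalization

**Positive factors.** fₗ = G / gₗ with gₗ the geometric mean of lane *l*'s
six spike-ins and G the geometric mean of all positive counts. By
construction the geometric mean of the factors is exactly 1 (tested to
1e−12). Factors outside [0.3, 3] flag the lane for removal. A zero positive
count is an input error (geometric mean undefined) and names the lane.

**Background.** bₗ = arithmetic mean of the lane's eight negative-control
counts; corrected value = max(count − bₗ, 0). A corrected value of exactly
zero is recorded as *missing* — the probe failed to register above
background. Subtraction (rather than thresholding) keeps low-expression
distributions statistically usable.

**Content factors.** rₗ = geometric mean of the lane's own top-75 highest
endogenous+housekeeping values; factor = (geometric mean of r over lanes) /
rₗ, accepted in [0.1, 10]. Lanes with fewer than 75 nonzero content values
are unevaluable. Housekeeping-anchored factors exist behind
`content_basis="housekeeping"` but are off by default: a reference set must
demonstrate reproducibility before it can anchor a cohort, and small FFPE
stromal panels generally cannot show it. Spike-ins are never part of the
content pool. Factors are computed once across all evaluable lanes; gated
lanes are then removed without recomputing the grand mean, which preserves
the geomean-1 identity over the computed set and keeps the ledger
interpretable.

**Missing filters.** Entities with strictly more than 50 % missing values
are removed — samples then genes on the univariate path, genes then samples
on the TSP path — with the second pass computed on the matrix remaining
after the first. Every removal (factor gating included) lands in an
exclusion ledger with its reason, so input = surviving + ledger holds per
axis (tested).

**A gauge identity instead of strict rescaling invariance.** Multiplying
one lane's raw counts by c rescales every cross-lane geometric-mean anchor
by c^(1/L) (L lanes), so the fully normalized matrix changes by exactly
that one global constant rather than not at all. The property test asserts
this exact algebraic form and, as the consequence that matters, that every
scale-free statistic — p-values, q, AUC, log₂ ratios, the whole DE table —
is unchanged. No cross-lane anchor can do better; strict invariance is
achievable only for statistics that are themselves scale-free.

## Univariate testing

* **MWU**: exact enumeration when n₁+n₂ ≤ 12 with no ties, otherwise the
  normal approximation with tie and continuity corrections. The asymptotic
  p at the study's sizes (15 vs 18) agrees with a 10⁵-shuffle Monte-Carlo
  null within 0.01 (tested), and the empirical type-I rate on all-null
  cohorts sits inside the 99 % binomial band around 0.05 (tested).
* **Welch t**: t = (x̄−ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ) with Welch–Satterthwaite df.
  Zero variance in both groups resolves by the limit convention (p = 1 for
  equal means, else 0).
* **Dual-test rule**: a gene is called iff both p < α (default 0.05) — a
  deliberate conservatism for small cohorts, requiring medians and means to
  agree. Dual calls are provably a subset of each single test's calls.
* **FDR**: Benjamini–Hochberg step-up. The reported `q` adjusts the MWU
  p-values (the rank test is the primary inferential route); a Welch-based
  `q_welch` is computed and written but never drives calls.
* **AUC**: U/(n₁n₂) with midrank ties, folded to max(A, 1−A). Folding makes
  the report orientation-free; direction is carried by the sign of
  log₂(mean GP4 / mean GP3) (negative = higher in GP3).
* Missing values are dropped per gene (pairwise complete); genes left with
  fewer than two usable values in a group are skipped and logged.

## The TSP classifier

Score Δᵢⱼ = |P̂(Exp(i) > Exp(j) | GP3) − P̂(· | GP4)|, strict inequality;
within-sample ties count against the ordering (they matter because
background-corrected counts tie at 0). The search maximizes Δ over all
unordered pairs; ties are broken by the larger secondary rank score — the
between-class difference of the mean within-sample rank gap of the pair —
and finally lexicographically, making the search deterministic (verified
against an independent exhaustive enumeration on 50 random matrices). The
ordering rule votes the class with the larger conditional ordering
probability; prediction ties go to the training majority class and are
logged.

**Permutation significance.** Labels are reassigned uniformly at random
preserving group sizes; by default the full pair search is re-maximized per
permutation, which is the honest null for a selected-best statistic. A
fixed-pair mode rescores a single pair; for one pair the two-sided tail is
also available exactly: the number of ordered samples assigned to GP3 is
hypergeometric, and the tail sums its pmf over assignments at least as
extreme as observed. On the package's reference fixture (13 vs 18 samples,
ordering in 10 and 4) this exact tail is ≈ 0.0040, and the 10⁵-draw
Monte-Carlo estimate lands within 3 binomial SE of it (tested). The raw
estimate p = #{null ≥ observed}/n is reported alongside the
(#+1)/(n+1)-corrected value, which can never be zero.

## Synthetic cohorts

`simulate_cohort` draws, per lane *l* and content gene *g*:

* mean μ = λₗ · 2^(baseline_g + effect_g·[group B]), with lane factors λₗ
  log-normal (σ = 0.25 by default, or explicitly planted);
* counts negative-binomial with var = μ + φμ² (φ = 0.15 default; Poisson at
  φ = 0), then zero-inflated with dropout probability 0.10;
* negative probes Poisson(4); positive probes Poisson(230 · fM · λₗ), which
  puts the 128 fM spike-in near 3 × 10⁴ counts.

Defaults mirror the emulated study design: 20 GP3 + 21 GP4 lanes and a
102 + 5 probe panel. Unspecified baselines are drawn uniformly on log₂
counts 4–10, a low-input amplified-cDNA regime in which background-level
genes and heavy missingness — the reason the >50 % filters exist — occur
naturally. The distributional form is an assumption: the platform's counts
are overdispersed digital counts, and negative-binomial is the standard
model, but no claim is made that real stromal panels are NB. The generator
also omits probe cross-hybridization, lane position effects, and FFPE
fragmentation chemistry. Consequently, passing tests establish correctness
of the *computations* and calibration/power under a plausible noise model —
not that any particular biological cohort will reproduce a given gene list.

`construct_tsp_fixture` builds the exact two-gene geometry behind the
reference worked example: n_A, n_B samples with the ordering holding in
exactly k_A and k_B of them, strictly positive values, no within-sample
ties. With (13, 18, 10, 4) — the unique split consistent with 24/31 correct
rule classifications — the pair score is 0.547 and the exact permutation
tail ≈ 0.0040.

## Numerical conventions and test sizing

* Missing-fraction comparisons are strict (> 0.5); factor and
  binding-density ranges are inclusive of endpoints.
* Score comparisons in the permutation test use a 1e−12 tolerance so that
  rational scores on the 1/(n_A·n_B) grid compare exactly in floats.
* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; no global state. Identical seeds give bit-identical cohorts,
  permutation draws, and pipeline artifacts (tested byte-for-byte).
* The calibration suites use 20 null cohorts × 102 genes (2040 draws) for
  the type-I band, 100 seeded cohorts for effect recovery at |log₂FC| = 4.6
  with 15 vs 18 lanes, and 200-draw permutation samples at the study's
  13 vs 18 split for the KS uniformity check — sizes at which the checks
  are sharp while the whole suite stays quick. The KS check is run at
  13 vs 18 rather than a balanced split because the max-score null is
  lattice-valued; at 10 vs 10 its atoms (multiples of 0.1) are wider than
  any KS band, which is a property of the statistic, not an implementation
  artifact.

## Known limitations

* Factor gating removes lanes using factors computed before gating; a
  re-iterated scheme would shift surviving lanes' values by a common
  constant but not their ratios.
* The exact MWU path is limited to tie-free pooled samples of ≤ 12; all
  larger or tied cases use the corrected approximation.
* The permutation test's `search` mode re-maximizes over all pairs and is
  O(pairs × samples) per permutation; for panels far beyond ~10³ genes the
  fixed-pair mode or fewer permutations may be needed.
* RCC files carry no group-label field; the package's RCC writer stores the
  group in the Sample_Attributes `Comments` row, and the reader recovers
  it — a round-trip convention of this package, not a platform standard.
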