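# Methods

## Model and procedure

`modscan` treats a normalized (log-scale) expression matrix
**E** = {e_{g,n}}, G genes × N samples, as a sample from a gene-gene
dependence structure that may itself depend on the expression of individual
"modulator" genes.  For a candidate modulator *m* the samples are split into
an *m*-on group (top `fraction` of samples by *m*'s expression) and an
*m*-off group (bottom `fraction`), each of size k = ⌊fraction·N⌋.  The
screen asks whether the co-expression network computed in the two groups
differs more than expected when the split carries no information.

Group-wise Pearson correlations C_M(i,j) are mapped to normalized
interactions I_M = √(k−3)·atanh(C_M).  The variance-stabilizing property of
Fisher's z (var ≈ 1/(n−3) at group size n) makes each I_M approximately
standard normal around its population value, so interaction strengths are
comparable across datasets and group sizes.  The published form of the
transform, (√(N/4−3)/2)·ln((1+C)/(1−C)), is the k = N/4 case; the scale
generalizes to the actual per-group size because `fraction` is
configurable.

Four modularity parameters summarize *m*'s effect:

* **ACI** (parameter 1): mean of ΔI = ||I_on|−|I_off|| over all unordered
  pairs — a genome-wide average change in interaction magnitude.  The
  average runs over every pair 1 ≤ j < i ≤ G (minus exclusions below); the
  magnitude form means ACI is invariant to a global sign flip of the
  correlations and to swapping the groups.
* **Nodes, edges, connectivity** (parameters 2–4): size and density
  (average degree 2E/V) of the *core modulated network*, the graph of pairs
  passing the two pair-level thresholds described next.

### Pair-level test and score

Under the null that a pair has one population correlation in both groups,
I_on − I_off ~ N(0, 2).  The default MAGIC p-value is the two-sided normal
tail of |I_on − I_off| / √2 — the classical two-sample Fisher-z difference
test, which is calibrated (type-I rate ≈ α) for any shared population
correlation.  A `statistic="magnitude"` variant applies the same tail to
ΔI = ||I_on|−|I_off|| instead.  Because ||a|−|b|| = min(|a−b|, |a+b|) and
a−b ⟂ a+b for joint Gaussians, its rejection rate at nominal α is α² for
null pairs with ρ ≈ 0: the magnitude variant is provided for symmetry with
the ACI definition but is strongly conservative, which is why the signed
difference is the default.  (Measured on independent genes: rate 0.050 at
α = 0.05 for signed, 0.0026 for magnitude.)

The MAGIC score is an effect-size filter on the same pair: both I values
are projected back to the correlation domain at an assigned sample size N′
(default: the actual group size k) and the absolute difference
|C^adj_on − C^adj_off| must reach `magic_score_min`.  Two projections are
implemented.  `exact` (default) inverts the forward transform
algebraically: tanh(I/√(N′−3)).  `verbatim` reproduces the published
projection tanh(I)/√(N′−3); note it is not the algebraic inverse and
saturates at 1/√(N′−3) ≈ 0.12 at N′ = 71.5, so correlation-scale thresholds
like 0.4 are unreachable in that mode — it is retained for fidelity and
comparison, with thresholds to be chosen on its own scale.

An edge's direction is `on_intensified` when |C^adj_on| > |C^adj_off|,
otherwise `off_intensified` (red/green in the conventional network
rendering).

### Permutation null and empirical p-values

The observed parameters are compared with those obtained when the on/off
split is random.  Each of `n_perm` permutations shuffles the sample index
vector and takes the first/last k entries as the two groups, then computes
all four parameters on the *unpermuted* expression values.  This preserves
the co-expression structure — which is what gives the null its nonzero
mean — while destroying any link between the split and a gene.  (A joint
column permutation of the whole matrix would change nothing: every
correlation, and every partition re-derived from a permuted modulator row,
would be identical.  The randomized-partition reading is the only
informative one.)

Empirical p-values use the add-one rule p = (1 + #{null ≥ obs})/(1 + n_perm),
so p ∈ (0, 1], ties count against significance, and the smallest attainable
value is 1/(n_perm+1) — at 10,000 permutations, 9.999×10⁻⁵, which is what
makes a cutoff of 10⁻⁴ meaningful: it selects exactly the genes whose
observed value exceeds every null draw.  At a reduced permutation count the
cutoff must be scaled accordingly (10⁻³ at 1,000 permutations is the same
"beats every null" criterion); the screen leaves both knobs explicit.

Because the random partitions are independent of any candidate gene, one
shared null serves all candidates (`null_scope="shared"`, the default);
`"per-modulator"` rebuilds the null with the candidate's own pairs excluded
for exactness at G-fold cost.  The shared null averages over all G genes'
pairs while an observed profile excludes the modulator's own pairs — a
relative difference of 2/G in the eligible pair set, negligible at screen
scale.

### Screen, intersection, ranking

Every gene is profiled, the four per-parameter significant lists at the
empirical cutoff are intersected into the key-modulator set, and genes are
ranked by the average of the four parameter z-scores ((value − mean)/sd
across profiled genes; a log-scale option exists since the parameters are
approximately log-normal across genes, but raw values are the default).
Per-parameter ranks give rank 1 to the largest value with ties sharing the
minimal rank.  Candidate profiles are mutually independent, so results are
bitwise-identical for any batch size or worker count (asserted by test).

`sample_status` reports, per sample, how many modulators have that sample
in their on group, off group, or either ("effective").  The mean of n_on
over samples is exactly (#modulators)·k/N — e.g. 973 modulators at k = 71,
N = 286 give 241.5 — a useful orientation check on any cohort.

## Handling of degenerate inputs and numerical choices

* Correlations are clipped to |c| ≤ 1 − 10⁻¹² before atanh, so c = ±1 maps
  to a large finite interaction (~√(k−3)·14) instead of overflowing.
* A gene constant within a group has undefined correlations; all pairs
  touching it are excluded from the ACI average and edge calling for that
  partition.
* Pairs involving the candidate modulator itself are excluded by default
  (selection on the modulator's own expression distorts its correlations);
  `include_modulator_pairs=True` restores them.
* Partition ties at the k-th value are resolved by a stable sort on
  (expression value, sample order) — deterministic and documented.
* p-values are floored at the smallest positive double so they remain in
  (0, 1].
* Missing values are rejected at load time by default; an optional policy
  drops incomplete genes so the correlation code never sees missingness.
  Pairwise-complete correlations would silently change the group-wise
  correlation semantics, so they are deliberately not offered.
* Probe-level matrices are collapsed per gene to the probe with the largest
  coefficient of variation (sd/|mean|); zero-mean probes have undefined CV
  and are skipped; the default informativeness threshold `cv_min = 0`
  applies no filter, as no principled universal cutoff exists.

## Synthetic data: what it emulates and what it does not

The generator draws a planted modulator as a standard Gaussian and gives
each of its target pairs a conditional correlation of `rho_on` in the top
stratum of the modulator's values, `rho_off` in the bottom stratum, and a
linear interpolation across the middle (a step function is available) —
a dose-response caricature of continuous modulation with the top/bottom
contrast exact.  Disjoint pairs are built by closed-form Gaussian mixing;
components that share genes are drawn with a per-sample Cholesky of the
component correlation matrix, rejecting infeasible (non-positive-definite)
requests.  Background genes are independent (optionally equicorrelated at
`background_rho ≥ 0` via a common factor); `noise_sd` adds white noise,
attenuating all planted correlations by 1/(1+noise_sd²).

All marginals are Gaussian and noise is homoscedastic: the generator does
not emulate probe effects, batch structure, heavy tails, or count noise.
Tests passing on these matrices validate the statistics and the machinery,
not robustness to microarray artifacts.

The standard recovery benchmark (`benchmark_spec`: G = 300, N = 400, one
modulator, 100 pairs at rho_on = 0.7 / rho_off = 0, fraction 0.25) arranges
the pairs as three-gene cliques ("triangles").  The layout matters: with
disjoint pairs the true modulated network is a perfect matching, whose
connectivity is exactly 1.0 — the minimum over nonempty networks — so the
connectivity parameter carries no signal; open chains reach only 4/3, which
a chance two-edge path in a null network ties.  Triangles are positive
definite for any |ρ| < 1 (determinant (1−ρ)²(1+2ρ)) and give the true
network connectivity ≈ 2, cleanly separated from the null.  On this
benchmark with a shared 1,000-permutation null and the beats-every-null
cutoff (10⁻³), the planted gene is recovered as the unique key modulator
with ≥ 0.9 edge recall across seeds; the full run takes ~10 s on one CPU.

## Problem sizes used in the tests

The suite exercises the screen at G up to 300 and N up to 400 with 1,000
permutations (the recovery benchmark), calibration at G = 100 / N = 200
(≈ 15,000 pairs over three random partitions), and p-value uniformity at
G = 25 / N = 60 with a 1,500-draw null — sizes chosen so the complete suite
runs in well under a minute of compute per heavy test while keeping every
statistical margin wide.  Memory grows as ~9 G² doubles per partition
(all pairwise matrices held at once); a 5,000-gene screen is feasible but
the permutation null dominates runtime, which is precisely why the shared
null is the default.

## Known limitations

* Only the two extreme strata are compared; modulation that varies smoothly
  with the modulator's continuous expression is detected only through its
  top-vs-bottom contrast.
* Modulators are screened independently; joint or competing modulation of
  the same pairs is out of scope.
* The four parameters are correlated measures of the same phenomenon
  (pairwise correlations 0.6–0.95 on real cohorts); the four-way
  intersection is a robustness device, not four independent tests.
* Empirical p-values are bounded below by 1/(n_perm+1); claims beyond that
  resolution require more permutations, with linear cost.
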