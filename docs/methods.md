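# Methods

## Model and assumptions

An I×J contingency table holds non-negative integer counts O_ij with row
totals m_i, column totals s_j, and grand total n. The test statistic is
Pearson's χ² = Σ_ij (E_ij − O_ij)²/E_ij with E_ij = m_i·s_j/n and
v = (I−1)(J−1) degrees of freedom. Zero row or column margins make E_ij = 0
and the statistic undefined; the public API treats them as a hard error (no
continuity correction, no automatic dropping of rows/columns).

The privacy model is ε-differential privacy with the row margins m_i
published. Neighboring databases then induce tables differing by moving one
unit between two columns within one row. Publishing margins is the standard
assumption in this setting: margins are needed to interpret a χ² value at
all, and releasing them does not reveal individual cell values.

The degrees-of-freedom formula (I−1)(J−1) is the standard independence-test
convention. Rows are the public-margin dimension everywhere; the CSV reader
documents this because transposition changes the sensitivity.

## Global sensitivity

`randchidist_sensitivity` implements the closed form Δ_R (README). Ties for
the smallest margin are broken by the lowest row index; the formula depends
only on the two smallest values so the result is tie-invariant (property
tested). Δ_R reduces algebraically to the published 2×3 formula
(`yu_sensitivity`) and, with equal margins, to 4n/(n+2)
(`fienberg_sensitivity`); both reductions are verified to 1e−12 across
margin grids.

`brute_force_sensitivity` is the executable check of the closed form: it
enumerates every table with the given margins (weak compositions of each
m_i into J parts, lexicographic, chunked over the first row to bound
memory; guarded at 10⁷ tables) and every unit move, and maximizes
|χ²(D₁) − χ²(D₂)|. It evaluates χ² through the per-column identity
χ² = Σ_j (n·Q_j/s_j − s_j), Q_j = Σ_i O_ij²/m_i, which a unit test checks
against the direct definition, so a neighbor costs O(1) instead of O(IJ).

**Empty-column convention.** At an empty column the statistic is a 0/0
form. The default (`zero_columns="extend"`) assigns empty columns zero
contribution — the continuous limit, and the convention under which the
closed form's maximizing table pairs exist (they contain an empty spare
column whenever J exceeds the units available to fill it). With
`zero_columns="skip"`, pairs touching such tables are excluded, which can
only lower the maximum. Under the default the oracle equals the closed form
to 1e−9 on the full validation grid (I ∈ {2,3}, J ∈ {2,3,4}, m_i ∈ [2,6]).

## The privatized null distribution

The released statistic is χ²* = χ² + Laplace(β), β = Δ_R/ε. Under H₀ its
distribution is the convolution g_{v,Δ,ε} of the χ²_v density with the
Laplace density. The threshold t solves P_g(X ≥ t) = α (the equation is
read as solve-for-t given α, the only reading consistent with comparing χ²*
to t) and the private p-value is P_g(X ≥ χ²*). Both the p-value and the
decision come from the single noisy statistic, so one invocation spends
exactly ε; decision and p-value are coherent (reject ⟺ p ≤ α) because the
tail function is strictly decreasing.

Numerical scheme (see the module docstring in `private_null.py` for the
derivation):

* Upper tail via the exchanged-order integral with the closed-form Laplace
  survival function, split at μ = x. The pieces are the classical χ² tail,
  a rescaled χ² tail (exp(x/β)·κ^{−v/2}·S_v(κx), κ = 1 + 2/β, assembled in
  log space), and one finite integral I(x) = ∫₀ˣ f_v(μ)·e^{−(x−μ)/β} dμ.
  For x ≤ 0 the tail is exact: 1 − e^{x/β}·(1+2/β)^{−v/2}/2 (a Laplace
  transform of the χ² density). Results are clamped to [0,1].
* I(x) is integrated adaptively (scipy quad, absolute tolerance 1e−11 for
  tails, 1e−12 for densities; failures raise `QuadratureError` with the
  achieved estimate). When the boundary layer x/β is wide the v = 1
  endpoint singularity is removed by μ = y²; when it is narrow the
  integration runs in w = (x−μ)/β truncated near w ≈ 45, discarding mass
  below e⁻⁴⁰ of the total.
* Extreme arguments of the χ² log-tail (κx grows like 2x/β) underflow
  scipy's logsf; an asymptotic series for the upper incomplete gamma takes
  over beyond the representable range.
* The critical value is found by brentq on a bracket
  [−β·ln(1/(2α)) − 1, q_{χ²_v}(1−α) + β·ln(1/(2α)) + 1], expanded
  geometrically if a sign is missing (a bracket failure raises
  `BracketError`; it would indicate a quadrature fault). Roots are resolved
  to 1e−10 and memoized per (v, Δ, ε, α) within the process only — no
  persistent cache, to avoid stale-tolerance bugs.
* Laplace noise is never truncated; negative released statistics are
  in-domain for the tail function. Truncation would break the privacy
  proof.

Validation: normalization of g to 1e−6; the β→0 limit recovers the χ²
density, tail, and percentage points; the tail and critical values match
empirical quantiles of 10⁶–10⁷ draws of χ²_v + Laplace(β) within three
Monte Carlo standard errors across (v, β) ∈ {1,4,9} × {0.4,4,40}; and the
exchanged-order tail equals direct integration of the density.

## Mechanisms

All mechanisms take an explicit seeded generator and spend their full ε in
one invocation. Laplace variates come from inverse-CDF transformation of
uniforms (log1p form for precision near the median).

* **randchidist** — χ² + Laplace(Δ_R/ε) against the calibrated threshold;
  emits the private p-value.
* **randchi** — same released statistic against the classical percentage
  point. Its significance collapses for small ε because the threshold
  ignores the noise; kept as the ablation of the recalibration step.
* **randcell** — independent Laplace(2/ε) on every cell. If any noisy cell
  is below five the mechanism fails to reject (the rule-of-thumb check
  applies to the noisy cells — they are what a data analyst would see).
  Otherwise χ² is recomputed from the noisy table using its own margins
  (`use_true_margins=True` switches to the public margins); noisy values
  stay real-valued, nothing is rounded or clamped. Non-positive noisy
  margins yield a flagged fail-to-reject, not an exception.
* **mcindep** — per-cell Laplace(2/ε) release, then an independence
  multinomial is estimated from the noisy margins (floored at zero,
  renormalized; total rounded, at least 1) and n_mc reference tables are
  drawn from it (default max(⌈2/α⌉, 1000), required ≥ ⌈1/α⌉). If any raw
  sampled table has a cell below five the mechanism fails to reject.
  Otherwise each reference is perturbed with fresh same-scale Laplace noise
  so reference and observed statistics are comparable, and the observed
  noisy χ² is compared with the empirical (1−α) order statistic of the
  reference statistics (references whose noisy margins go non-positive
  count as +∞, keeping the quantile conservative). Two interpretive choices
  are deliberate: the full ε budget is spent on the observed-table noise
  with fresh same-scale noise on references, and the rule-of-thumb check
  applies to the raw sampled counts — applying it after perturbation
  would, at ε = 0.1, trip on some reference cell with probability ≈ 1
  regardless of n, making the mechanism vacuous, which contradicts its
  observed large-n power.
* **nonprivate** — the classical test.

A histogram-ratio check on 10⁶ released statistics for a fixed neighboring
table pair confirms the e^ε bound empirically.

## Simulation harness

Tables are drawn from Multinomial(n, p) over the I·J cells. The generator
conditions on positive margins by resampling (the statistic is undefined
otherwise); redraw counts are reported in every summary so the
conditioning's (tiny) effect is visible. The study designs the harness
reproduces:

* significance: uniform 2×2 (p = 0.25 each) and uniform 4×4 (1/16 each);
* power: 2×2 with (0.25±0.01) and (0.25±0.15) diagonal perturbations, the
  unbalanced (0.3±0.15 / 0.2±0.15) design, and a 3×4 design perturbing
  four cells of a uniform 1/12 base by ±0.07 — all expressed through
  `effect_probs(base, delta, pattern)` with patterns in {−1, 0, +1};
* a synthetic correlated-pair generator (`correlated_pair_probs`) blending
  an independence outer product with a diagonal coupling, standing in for
  two-locus association tables built from real genotype data.

Defaults are the study conditions: n ∈ {100, 300, 500, 700, 900}, 1000
replicates per grid point, α ∈ [0.005, 0.05], ε ∈ [0.01, 10] with 0.1 the
focal value. No multiple-testing correction is applied; each test is
treated as independent. The rule-of-thumb pre-filter on generated tables
(resample until all cells ≥ 5, the protocol used with real genotype data)
is exposed as `min_cell_filter` and off by default, since the synthetic
designs do not state it.

Within a replicate every requested mechanism runs on the same table
(paired design, chosen for variance reduction in mechanism comparisons)
but draws noise from its own substream, keyed by a canonical mechanism
index — so the table sequence and each mechanism's results are invariant
to which other mechanisms a run requests. `truth` (null vs alternative) is
derived from whether the cell probabilities factorize into their margins;
a contradicting label is a configuration error. Mechanism failures are
counted per cell and reported, never silently dropped.

Sanity anchors: the non-private test attains the nominal level under the
null; the calibrated private test holds it at ε = 0.1 on both 2×2 and 4×4
nulls; rand_chi and rand_cell fall far below 1−α; mcindep holds the level
but loses power at small n, where randchidist is at least as powerful.

What passing these simulations does *not* show: behavior on real genotype
tables (cell distributions there are not multinomial-uniform), robustness
to misspecified public margins, or any guidance on choosing ε.

## Problem sizes

The validation suite uses 2000 replicates per grid point for the type-I
experiments, 500 for the mechanism-ordering comparisons, 10⁶ draws for
sampling-oracle checks (10⁷ for the density spot check), and the full
I ∈ {2,3}, J ∈ {2,3,4}, m_i ∈ [2,6] grid for the oracle-equivalence sweep.
`scripts/acceptance.py` uses 2000 replicates per point for the type-I
targets and 1000 for the power target.

## Known limitations

* Row margins must be public; sensitivity with private margins is out of
  scope, as are statistics other than Pearson's χ² (no Yates correction,
  Fisher's exact test, or G-tests) and (ε,δ)-relaxations or local-model
  mechanisms.
* The calibration treats the χ²_v law as the exact null of the true
  statistic; at very small n the multinomial discreteness makes the true
  null only approximately χ²_v, so empirical type-I error can sit a few
  tenths of a percent off α (the same approximation the classical test
  makes).
* The brute-force oracle is exponential in I and J; it is a validation
  tool for small margins, not a production sensitivity computation.
* mcindep follows the published description operationally but the original
  work leaves budget-splitting details unstated; the choices above are
  flagged where made.
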