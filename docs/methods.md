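# Methods

## Problem and model

A sample of angles φ₁,…,φₙ is tested against the null hypothesis of
circular uniformity: density 1/2π everywhere on the circle. All internal
computation uses radians on [0, 2π); degrees are converted at the I/O
boundary. Two data regimes are distinguished:

- **continuous** data, where ties have probability zero;
- **grouped** data, restricted to m evenly spaced values (grouping
  resolution m, e.g. m = 36 for measurements to the nearest 10°, m = 72
  for 5°). Grouping is modelled as rounding a continuous draw to the
  nearest multiple of 2π/m, which is how rounded field measurements arise.

The test statistics are the classical ones (see the README for formulas).
All of them reject for large values. Design points worth stating:

- The Hermans–Rasson double sum runs over **all** (i, j) pairs including
  i = j; each diagonal term contributes the constant π/2 + 2.895·(2/π).
  Excluding the diagonal would shift the statistic by a constant and leave
  Monte-Carlo p-values unchanged, but the full sum is the form implemented.
- Kuiper's statistic carries the √n factor (Vₙ = √n(D⁺ + D⁻)) so that the
  classical critical-value tables apply directly; any monotone rescaling
  would give identical Monte-Carlo p-values.
- The Gini statistic is evaluated through the sorted-spacings identity
  Σᵢ<ⱼ|Tᵢ−Tⱼ| = Σₖ(2k−1−n)T₍ₖ₎ (O(n log n)); an explicit O(n²) double-sum
  path exists and the two are required by tests to agree to 1e-12.
- The chi-squared baseline is the plain Pearson X² against equal expected
  counts n/m over all m bins (empty bins included), df = m−1, no continuity
  correction, and is restricted to n > 5 — below that the reference
  distribution is meaningless for such sparse tables.

## P-values

- **Rayleigh**: the standard second-order series approximation in
  S = nR̄² (accuracy well below 1e-3 for n ≥ 10; clamped into (0, 1]).
  A Monte-Carlo route for the Rayleigh statistic also exists and the two
  agree within Monte-Carlo error (tested).
- **Kuiper/Watson table bounds**: optional range statements ("p > 0.15")
  from the classical modified-statistic critical-value tables, provided
  because small-sample practice often reports them; point p-values come
  from the Monte-Carlo engine.
- **Monte-Carlo**: p = (N_e + 1)/(N_R + 1), where N_e counts simulated
  statistics **greater than or equal to** the observed one among N_R
  simulated uniform samples of the same size. p is therefore in
  [1/(N_R+1), 1] and valid (never anti-conservative in expectation).
  Default N_R = 10,000.

### The tie-breaking (TB) variant

Grouped data defeat the continuous-null Monte-Carlo test because the
observed statistic is computed on tied data while the null statistics are
not. The TB procedure:

1. perturb every observed angle by i.i.d. von Mises(0, κ) noise
   (default κ = 1000, circular sd ≈ 1.8°), wrapping into [0, 2π);
2. simulate each null sample as continuous uniform → **round to the data's
   grouping resolution m** → perturb with the same κ;
3. apply the Dwass rule as usual.

Step 2's rounding is essential and deliberate: with an unrounded null the
spacing tests still inflate on grouped data (measured ≈ 0.10–0.13 type-I at
n = 50, m = 36 instead of 0.05), because a perturbed grouped sample retains
cluster structure that a continuous uniform sample lacks. With the mirrored
pipeline the observed and null samples are exchangeable under uniformity,
so the TB p-value is exactly valid at any n. The same convention explains
the TB tests' behaviour on *continuous* data: they assume a grouping
(m = 36 by default when the sample declares none) that is not there, making
them increasingly conservative as n grows.

κ trades tie-breaking strength against distortion: it must be large enough
that perturbations are far below the grouping resolution and small enough
to actually separate ties. κ = 1000 suits 10° grouping; the TB p-value on
continuous data converges to the standard Monte-Carlo p-value as κ → ∞
(tested at κ = 10⁸).

Each TestResult carries its seed; the observed-sample perturbation and the
null stream are independent children of that seed, so results are exactly
reproducible.

## Alternative distributions

The power study draws from twelve alternatives (parameters in
`distributions.ALTERNATIVES`): von Mises κ=1; wrapped linear skew normal
(dispersion 1, shape 30); symmetric/asymmetric bimodal von Mises mixtures
(κ=5, modes 0°/180° and 0°/120°); symmetric/asymmetric trimodal mixtures
(κ=10, modes 0°/120°/240° and 0°/90°/200°); cardioid ρ=0.3; Kato–Jones
r=0.7, κ=2.3; circular triangular ρ=0.3; wrapped Cauchy ρ=0.7; wrapped
normal; wrapped stable (scale 1, index 0.3, skewness 1).

Implementation notes:

- von Mises draws use numpy's generator (Best–Fisher rejection); skew
  normal and wrapped Cauchy use scipy's samplers, wrapped mod 2π.
- Cardioid and triangular densities are bounded, so both use simple
  rejection sampling from a uniform envelope; the triangular density
  (1/8π)(4 − π²ρ + 2πρ|π − θ|) has resultant length exactly ρ, which the
  calibration tests exploit.
- Wrapped stable uses a hand-written Chambers–Mallows–Stuck transform in
  the 1-parameterization, wrapped mod 2π; tests cross-check it in
  distribution against scipy's independent stable sampler.
- Kato–Jones is generated as a Möbius transformation of a von Mises draw
  (e^{iX} = (e^{iΘ} + r)/(re^{iΘ} + 1), Θ ~ vM(0, κ)); with no external
  reference generator available it is validated structurally: centred at
  its mode, clearly non-uniform, and collapsing to the von Mises at r = 0.
- The wrapped normal's σ is not pinned by the study design; σ = √(−2 ln 0.7)
  ≈ 0.845 was chosen once so its resultant length (e^{−σ²/2} = 0.7) matches
  the wrapped Cauchy scenario, making the two heavy/light-tail cases
  comparable.

## Simulation experiments

A study cell is (test, variant, distribution, n, grouping). For each cell,
`n_datasets` samples are drawn (continuous draw first, then rounding, when
grouped), tested at α = 0.05, and the rejection fraction recorded.

**Shared-null acceleration.** All datasets in a cell share one simulated
null distribution of `n_reps` statistic values: every dataset in the cell
has the identical null pipeline, so the per-dataset p-values remain valid
and the rejection-rate estimand is unchanged; only a small correlated noise
component is introduced through the shared null's quantile error
(SE ≈ √(α(1−α)/n_reps)). `paranoid=True` re-simulates the null per dataset
and agrees within Monte-Carlo error (tested). Per-cell seeds are derived by
hashing the cell coordinates with the master seed, so any cell reproduces
in isolation.

**Problem sizes.** Defaults are desk-scale: n ∈ {5, 10, 15, 25, 50},
m = 36, 2,000 datasets and 2,000 null replicates per cell (the experiments
are also run at 10,000/10,000 via `--scale full`; the desk scale keeps a
full grid to a few minutes and leaves rejection-rate standard errors near
0.005, ample for the effects of interest, which are 0.05 vs 0.5+).

**What the generator emulates — and does not.** Synthetic grouping is
exact rounding with a half-up tie rule at bin midpoints (a documented
convention; it affects only a measure-zero set of continuous inputs).
Real instruments may round asymmetrically, drift, or mix resolutions
within one dataset; heaping (preference for "round" values like 0°/90°)
is not modelled. Passing tests therefore demonstrate correctness under
clean, single-resolution rounding, not robustness to every field artefact.

## Numerical and reporting choices

- Rounding ties at bin midpoints go half-up (toward the larger multiple);
  sorting is stable; zero spacings from ties are legal values, not errors.
- n = 1 samples are accepted by `normalize` (and by the HR and Rayleigh
  statistics, which are defined there) but rejected by anything
  spacing-based.
- The chi-squared type-I rate is genuinely conservative at small n with
  many bins (≈ 0.037 at n = 15, m = 36, where the expected count per bin
  is 0.42): "control" for this test means it does not inflate, and its
  tests check exactly that.
- The Rayleigh test's power against a perfectly balanced bimodal
  alternative is slightly *above* α (≈ 0.06 at n = 50) even though the
  alternative's resultant length is zero — the data are still non-uniform —
  so "no useful power" is asserted with a small systematic allowance on top
  of Monte-Carlo slack.
- A single TB run is random through the observed-sample perturbation: on
  the pigeon data its p-value has per-run sd up to ≈ 0.02 (Rao, Kuiper,
  Gini), far above the binomial floor √(p(1−p)/N_R) ≈ 0.0025. Where a
  central TB p-value is reported (the example-reproduction script), it is
  the **median** over many independent replicates of the full procedure:
  the p distribution is right-skewed, and the median is the best predictor
  of what any single run — including a previously published one — looks
  like. Replicate counts are stated next to each reported number.

## Known limitations

- Axial (period-π) data, weighted observations and multi-sample tests are
  out of scope.
- No asymptotic distribution theory for the Gini and HR statistics:
  p-values for them are Monte-Carlo only.
- The Kato–Jones generator follows the Möbius construction with mean
  direction fixed at the mode; it is validated by distributional properties
  rather than stream-for-stream against any external implementation.
- Table-bound p-values cover only the tabulated significance levels and
  are intentionally coarse.
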