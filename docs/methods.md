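# Methods

This note documents the statistical model, the estimation procedure, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Model

Ratings are analysed on the coded [0, 1] scale: the 5-point Effective scale
is coded {0, 0.25, 0.5, 0.75, 1} and the Genuine/Pleasant sliders are
continuous, with 0.5 the neutral point in all three.  Each response is
modelled separately by a Gaussian mixed-effects SSANOVA

    y_ij = η(x_ij) + b_i + ε_ij,   b_i ~ N(0, θ²),  ε_ij ~ N(0, σ²),

where η decomposes into functional-ANOVA terms, each living in the
reproducing-kernel Hilbert space of its marginal (or tensor-product) kernel:

- **Cubic kernel** on [0, 1] for continuous covariates (age 18–82, drinks
  0–5, delay 0–200 ms, each affinely rescaled using the declared design
  range).  Closed form k(x,z) = k₁(x)k₁(z) + k₂(x)k₂(z) − k₄(|x−z|) with
  k_r the scaled Bernoulli polynomials; the penalty null space {1, x} is
  carried as unpenalized columns, so straight lines are never shrunk.
- **Nominal (shrinkage) kernel** I(x=z) − 1/K for gender.
- **Ordinal kernel** for the three-level spatial factors, defined
  constructively as the Moore–Penrose inverse of the first-difference
  penalty matrix on level scores.  This guarantees symmetry, positive
  semi-definiteness, centering (zero row sums over levels) and a penalty
  that grows with squared level differences; any scale difference from
  other published ordinal-spline forms is absorbed by the term's smoothing
  parameter.
- **Tensor products** of the ordinal kernels for the two- and three-way
  spatial interactions.

All discrete kernels are centered, and the cubic kernel integrates to zero
over [0, 1] in each argument, so every term is identifiable against the
intercept and interactions are identifiable against their marginals.

Candidate smile-effect decompositions form the hierarchical nine-model
lattice from the full model (three mains, three two-ways, the three-way)
down to the additive model; the three-way term is admitted only alongside
all three two-ways.

## Estimation

**Step 1 — REML for θ².**  A working linear mixed model with participant
random intercepts and a saturated parametric proxy for the fixed effects
(cell-mean dummies for the 27 smiles or 6 delays, linear age and drinks, a
gender dummy) yields REML estimates of (θ², σ²).  The random-intercept
structure admits an exact one-dimensional profiled REML: β and σ² are
profiled out analytically and the criterion is minimized over log γ
(γ = θ²/σ²) by bounded scalar search with an explicit boundary check at
γ = 0.  Because the proxy uses cell-mean stimulus dummies, it is identical
for all nine candidate models, so θ² is estimated once per (data, response)
and shared across the lattice.

**Step 2 — penalized fit with GCV.**  With V = I + γZZ′ fixed, responses and
basis are whitened blockwise by V^{−1/2} (cheap per participant), and the
representer problem is solved on all distinct covariate values as knots
(exact at this scale; no low-rank approximation).  Each penalized term
carries its own smoothing parameter λ, and the vector λ minimizes
V(λ) = n·RSS(λ)/(n − tr S_λ)².  The optimizer is deterministic: a
coordinate-wise coarse-grid pre-scan (log λ ∈ [−12, 12], step 1.5, two
sweeps, started from log λ = 0), a joint Nelder–Mead polish, and a
coordinate-wise Brent refinement.  The pre-scan and refinement exist because
a lone simplex search from a fixed origin lands in different quasi-optima
for different candidate models, which corrupts information-criterion
comparisons between models that are near-equivalent after shrinkage.

Numerical safeguards: each kernel penalty block is eigen-reduced to the
kernel's range (centered kernels carry an exact null direction), which makes
the penalized system positive definite; log λ is clamped to ±40 (numerically
zero/infinite smoothing); the Cholesky solve performs one step of iterative
refinement, and a tiny relative ridge (1e−10) with a warning is the fallback
for near-singular systems.

**Derived quantities.**  edf = tr S_λ; σ̂² = RSS_whitened/(n − edf); BLUPs
b̂_i = (γn_i/(1+γn_i)) × (mean residual of participant i); ρ = θ̂²/(θ̂²+σ̂²);
R² and R*² are squared Pearson correlations of the response with the fitted
fixed part, without and with b̂_i.  The marginal Gaussian log-likelihood is
evaluated blockwise at (θ̂², σ̂²), and AIC = −2ℓ̂ + 2·df,
BIC = −2ℓ̂ + log(n)·df with df = edf + 2 (the two variance parameters).
Absolute score values are convention-dependent (published tables add an
arbitrary constant); only within-response differences are meaningful, and
model selection uses them.  Selection returns the AIC (or BIC) minimizer;
score differences below 0.01 — far beneath any evidence threshold and at the
resolution of the λ search — count as ties and resolve toward parsimony.

**Bayesian intervals.**  The posterior covariance of the coefficient vector
is σ̂²(B̃′B̃ + Λ)^{−1} (Wahba-type, with flat priors on the unpenalized
columns); an effect function's pointwise 90% interval is its posterior mean
± 1.645 × posterior SD.  These intervals carry the classic across-the-
function calibration property: their average coverage is close to nominal,
with undercoverage concentrated at curvature extrema of the true function
(measured in this package's own calibration test; see Limitations).

**Delay summaries.**  η̂_T is the centered delay effect (zero uniform
integral over the rescaled [0, 1] axis).  Effect sizes d̂ = η̂_T(200)/σ̂ and
d̂* = [η̂_T(75) − η̂_T(200)]/σ̂ are reported by default with η̂_T referenced to
delay 0 (η̂_T(0) := 0), the convention matching "units below the symmetric
smile"; the raw centered convention is available (`reference="centered"`),
and d̂* is identical under both.  The zero crossing is the first point after
the curve's early maximum where the delay-0-referenced curve returns to
zero, linearly interpolated on a 1 ms grid.

## Synthetic-data generator

The generator emulates the rating study's design: 802 participants (510
female, 292 male), integer ages from an equal-weight two-component normal
mixture (means 20 and 50, SDs 4 and 12, truncated to [18, 82]) chosen to
match the reported bimodal age distribution; drinks 0–5 with a monotone
decreasing distribution (0.55, 0.20, 0.12, 0.07, 0.04, 0.02), as most
fairgoers reported none.  Each participant rates 15 animations sampled
without replacement from 32 distinct stimuli: the 27 factorial smiles plus
five delay variants (25–200 ms) of smile 22, whose 0 ms variant is smile 22
itself.  Smile numbering follows the published figure order
(index − 1 = 9·angle + 3·dental + extent over 0-based levels), which is the
only mapping consistent with the published descriptions of smiles 21, 22,
24 and 27; it is configuration-overridable.

The ground truth is built from explicit centered ANOVA components so its
decomposition is known exactly: main effects favouring medium-to-high angle
with low-to-medium extent; an angle×extent component penalizing extreme
combinations; dental-show two-ways making more dental show helpful at high
angle/extent and harmful at low; and a genuine three-way component
(−0.05·a_c·e_c·d_c on centered level scores) that switches the dental-show
effect's sign across the angle–extent plane, as the study's heat maps show.
The delay curve is a monotone-segment PCHIP through
(0, 0), (25, 0.03), (50, 0.04), (75, 0.035), (100, 0.02), (125, 0),
(150, −0.035), (200, −0.09): a positive bump at slight asymmetries, a zero
crossing at 125 ms, and a −0.09 deficit at 200 ms.  Default variances are
θ² = 0.011, σ² = 0.042, the midpoints of the study's reported ranges; a
small quadratic age effect (≈ ±0.03) peaks in middle age, and gender/drinks
effects are zero.  Emotion selections are independent Bernoulli draws per
label with Happiness tracking smile quality and Contempt elevated for
low-angle/low-extent smiles (an empty selection is replaced by the modal
emotion, as the survey required at least one choice).  Effective responses
are snapped to the 5-point grid; sliders are clipped to [0, 1] at double
precision.

What the generator does **not** emulate: correlation of a participant's
baselines across the three response scales (each response draws independent
b_i); participant-specific scale usage (variance heterogeneity); any
stimulus random effects; the 5 still-image trials; and ratings of
animations outside the 33 analysed stimuli.  Consequences are visible in
the dual R²: the generator reproduces the study's R² (≈ 0.10 for the
symmetric Effective analysis) but its R*² tops out near 0.35 under a purely
Gaussian random-intercept model with ρ ≈ 0.23, whereas the real data reach
≈ 0.47 — real participant effects are richer than the model's Gaussian
intercepts.  Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated model, not that the model captures
every feature of real raters.

## Simulation sizes in the test suite

Variance-component recovery (20 seeds), delay zero-crossing recovery
(10 seeds) and interval calibration (200 replicates) run at the full study
size of 802 × 15 ratings.  The nine-model lattice selection simulations run
at 250 participants for 10 seeds per condition, enough for the ≥ 80%
selection-consistency checks while keeping the suite quick.

## Known limitations

- Pointwise Bayesian intervals undercover at curvature extrema of the delay
  curve (measured mean coverage 0.83 at the interior delays at full study
  size, versus 0.90 nominal), the expected behaviour of Wahba-type intervals
  under smoothing bias; simultaneous bands are out of scope.
- The zero-crossing estimator inherits the same smoothing bias and sits
  slightly early on average (≈ 112 ms when the true crossing is 125 ms).
- Gaussian likelihoods are used for the discretized Effective response; an
  ordinal-likelihood model is out of scope.
- Absolute AIC/BIC values are not comparable across implementations (df and
  likelihood conventions differ); only the selection ordering is.
- The REML working model assumes linear age/drinks fixed effects; strong
  nonlinearity there would leak into σ̂² (not θ̂², which is protected by the
  cell-mean stimulus dummies).
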