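# smilespline

Mixed-effects smoothing-spline ANOVA (SSANOVA) for smile-perception rating
studies.

## The problem

Which spatial properties of a smile (mouth angle, smile extent, dental show)
and which temporal properties (the left–right onset delay asymmetry) make a
smile read as *effective*, *genuine* and *pleasant*?  Rating studies answer
this with repeated judgements: hundreds of participants each rate a sample of
computer-animated smiles on coded [0, 1] scales, so the data are long tables
of (participant, stimulus) ratings with strong participant-level baseline
differences.  `smilespline` is for analysts of such studies: it fits
nonparametric mixed-effects models of the ratings, selects among candidate
interaction structures, and reports effect functions with Bayesian
uncertainty.

## The model

A rating by participant *i* of stimulus *j* is modelled as

    y_ij = η_A(a_i) + η_G(g_i) + η_D(d_i) + η_S(s_ij) + b_i + ε_ij

with b_i ~ N(0, θ²) participant random intercepts and ε_ij ~ N(0, σ²).  The
covariate effects use cubic smoothing splines (age, drinks) and a nominal
shrinkage spline (gender).  For spatially varied ("symmetric") smiles the
smile effect decomposes functionally,

    η_S(s) = η_0 + η_1(s_1) + η_2(s_2) + η_3(s_3)
           + η_12 + η_13 + η_23 + η_123 ,

with ordinal smoothing splines for the three-level factors and tensor-product
reproducing kernels for the interactions; nine hierarchical candidate
decompositions are scored by AIC/BIC.  For delay-asymmetry variants the smile
term is replaced by a cubic spline η_T(t) in the onset delay (0–200 ms).

Estimation is two-step: (1) exact profiled REML for θ² under a saturated
parametric working model; (2) penalized weighted least squares on whitened
data with one smoothing parameter per term, chosen by generalized
cross-validation, V(λ) = n·RSS(λ)/(n − tr S_λ)².  Inference uses the Bayesian
interpretation of the smoothing spline: 90% pointwise intervals are
estimate ± 1.645 × posterior SD.  Derived summaries include the intra-class
correlation ρ = θ²/(θ² + σ²), the dual R² pair (fitted values without / with
the BLUPs b̂_i), delay effect sizes d̂ = η̂_T(200)/σ̂ and
d̂\* = [η̂_T(75) − η̂_T(200)]/σ̂, and the "successful smile" rule (all three
predicted ratings strictly above the neutral 0.5).

A synthetic-data generator reproduces the study design — 802 participants
(510 F / 292 M, bimodal ages peaking near 20 and 50), 15 animations per
participant from 27 factorial smiles plus delay variants of the prototype
smile 22 — so the whole pipeline is testable without the original data.

## Worked example

```python
import smilespline as sp
from smilespline import pipeline
from smilespline.effects import delay_zero_crossing

cfg = sp.StudyConfig()                      # the real study's design
truth = sp.default_truth(cfg)
data = sp.generate_ratings(cfg, truth, seed=1)

sub = pipeline.asymmetric_subset(data)      # smile-22 delay variants
spec = sp.ModelSpec("pleasant", "asymmetric")
theta2, sigma2 = sp.estimate_random_intercept(sub, spec)
res = sp.MixedSSANOVA(sub, spec).fit(theta2=theta2, sigma2=sigma2)
print(res.summary())
es = res.effect_sizes()
print(f"d = {es.d:.3f}, d* = {es.d_star:.3f}, "
      f"zero crossing = {delay_zero_crossing(res):.1f} ms")
```

prints

```
Mixed-effects SSANOVA results
==============================================
response:        pleasant
stimulus model:  asymmetric
terms:           age, gender, drinks, delay
n obs:           2268
n participants:  788
----------------------------------------------
edf (tr S):            7.46
sigma2:              0.0371
theta2:              0.0105
rho (ICC):           0.2214
R2 / R*2:            0.0450 / 0.4564
logLik:              291.88
AIC / BIC:          -564.83 / -510.64
----------------------------------------------
smoothing parameters (GCV):
  age                      5.1647e-04
  gender                   7.5596e+10
  drinks                   1.2423e-03
  delay                    1.4012e-04

d = -0.489, d* = 0.626, zero crossing = 111.5 ms
```

Reading the output: participant baselines account for ρ ≈ 22% of rating
variance; the fixed effects alone explain R² ≈ 4.5% but R\*² ≈ 46% once each
participant's baseline is included.  The fitted delay effect shows the
characteristic pattern — a slight asymmetry helps, but beyond the zero
crossing (here ≈ 112 ms, truth 125 ms) the smile degrades, reaching a
medium negative effect size (d ≈ −0.49) at a 200 ms delay, while the drop
from the best slight asymmetry to 200 ms is medium-large (d\* ≈ 0.63).

The nine-model spatial analysis and the emotion table run the same way:

```python
report = pipeline.run_symmetric_analysis(data)       # Table-2/3 analogues
emo = sp.emotion_percentages(data)                   # 7 x 27 percentages
```

or from the shell:

```sh
smilespline simulate --seed 1 --out ratings.csv
smilespline analyze-symmetric ratings.csv --out-dir results
smilespline analyze-asymmetric ratings.csv --out-dir results
smilespline emotions ratings.csv --out results/emotions.csv
```

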