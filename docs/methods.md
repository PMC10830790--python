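# Methods

This note records the statistical model behind `isobolkit`, the choices
made where the conventional methodology leaves room, and what the
synthetic-data validation does and does not demonstrate.

## Quantal dose-response model

An MES-type screening assay yields, per dose group, the number of
animals protected out of those tested (8 per group; 2–3 groups per
determination). We model protection as independent Bernoulli trials
with

P(protection | dose d) = Φ(β₀ + β₁ log₁₀ d),  β₁ > 0,

and estimate (β₀, β₁) by maximum likelihood. The classical
computer-assisted log-probit procedure of the screening literature is a
graphical/nomogram method; ML probit regression is its statistically
efficient, exactly specifiable modern equivalent, and is what we
implement. We do not claim the two produce identical standard errors.

* **Optimizer.** Newton–Raphson with analytic gradient and Hessian and
  step halving, started from the least-squares line through the
  empirical probits of non-extreme groups; convergence requires a
  log-likelihood change below 1e-8 and a small gradient norm. If Newton
  stalls, a BFGS polish runs; persistent failure is reported as
  `converged = False` rather than silently returned, and downstream
  ED50 extraction refuses such fits.
* **Covariance.** Inverse observed information at the optimum.
* **Separation.** If every group responds at 0% or 100% the likelihood
  has no finite maximizer and a `SeparationError` is raised. Extreme
  groups alongside interior ones are retained in the likelihood (they
  carry information); no continuity corrections anywhere.
* **ED50 and SEM.** ED50 = 10^(−β₀/β₁). The variance of
  log₁₀ ED50 = −β₀/β₁ follows the delta-method ratio rule; the SEM on
  the dose scale is ED50 · ln 10 · SE(log₁₀ ED50). Against a 10,000-
  resample parametric bootstrap on a 4-group fixture the delta SEM
  agrees within ~7%.
* **Effective n and df.** A dose group counts toward `n_effective` when
  its *observed* proportion lies strictly inside (Φ(−1), Φ(1)) ≈
  (0.1587, 0.8413) — the 4th-to-6th-probit window of screening tables.
  Open vs closed endpoints is immaterial at n = 8 per group, since
  k/8 can never equal the boundary values. Each estimate carries
  df = n_effective − 2 (two parameters consumed by the line); in the
  degenerate simulated case n_effective < 3 the df floors at 1 so that
  downstream Welch combinations stay defined. Bundled reference
  determinations all have n_effective ≥ 16.

## Summary-statistic inference

Published tables provide (mean, SEM or SD, n) triples; the dispersion
tag is always explicit, never inferred. ED50 tables are SEM-tagged and
reconstructed as SD = SEM·√n with n the tabulated (probit-window)
group size; this convention exactly reproduces the reference tables'
printed F statistics, confirming it matches what standard bioassay
software does.

* **ANOVA.** One-way fixed-effects from summaries; identical to the
  raw-data ANOVA for any samples carrying the stated moments (checked
  to 1e-10 in the suite via exact-moment sample construction).
* **Dunnett.** t_i = (m_i − m₀)/√(MS_within(1/n_i + 1/n₀)) with the
  ANOVA error term; two-sided p-values from the equicorrelated
  multivariate-t distribution (scipy's implementation, seeded),
  evaluated on exact-moment reconstructed samples. Significance is
  flagged at 0.05 and 0.01, matching the star convention of the
  reference tables.
* **Welch's t** (used for ED50_mix vs ED50_add): t = Δm/√(SEM₁²+SEM₂²),
  Welch–Satterthwaite df over the per-estimate df (n_effective − 2 for
  ED50s). **Pooled t** (brain concentrations): classical two-sample
  pooled-variance test, df = n₁ + n₂ − 2, which reproduces the
  reference t₁₄ values.
* Two-sided tests throughout; signed t reported, classification on |t|.

## Isobolographic transformation

For an adjunct fixed at dose d with single-drug estimate ED50_A:

ED50_add = ED50_V (1 − d/ED50_A),
Var = (1 − d/ED50_A)² SEM_V² + (ED50_V d / ED50_A²)² SEM_A²,

assuming independent errors and constant relative potency (parallel
log-probit curves) — the standard fixed-dose Loewe form. The df of the
prediction combines the two variance components by Welch–Satterthwaite.
Classification uses Welch's t at α = 0.05: additive when p ≥ α, else
supra-/sub-additive by the sign of ED50_mix − ED50_add. Isobologram
coordinates are exported with the adjunct on X and the varied drug on
Y; A points satisfy the line identity to machine precision by
construction.

## Synthetic-data generator

The generator emulates the experiment the analysis assumes, not the
biology underneath it:

* Single drugs: Bernoulli draws under the probit model at a geometric
  dose grid (spacing factor 2) centered on the true ED50, 3 levels of
  8 animals by default. The default slope is **3 probits per decade**:
  under spacing-2 placement this puts the outer groups at ~18%/82%
  expected response — inside the probit window — so simulated
  determinations carry 16–24 in-window animals, the pattern real
  screening tables report. Steeper slopes under the same spacing
  drive the outer groups to near-0/100% and leave effectively one
  informative group, which is not what the emulated assays look like.
* Combinations: protection = Φ(slope_V · log₁₀(L/γ)) with L the Loewe
  sum d_V/ED50_V + d_A/ED50_A and γ the interaction index (γ = 1
  additive, < 1 synergy, > 1 antagonism). The mixture inherits the
  varied drug's slope (the parallelism assumption of the additive
  formula). Default mixture doses center on the true combination ED50
  ED50_V(γ − f), mirroring the adaptive dose-ranging of a real
  determination; γ ≤ f is rejected.
* Brain concentrations: independent normals, untruncated (negative
  draws are negligible at the small CVs of concentration tables, and
  truncation would bias t-test calibration checks).
* All randomness flows through one `numpy.random.Generator`; equal
  seeds give bit-identical experiments.

### What the validation shows

At the screening design (3 × 8, spacing 2, slope 3, ED50 8.27 mg/kg),
2,000 simulated determinations give median relative ED50 bias ≈ 0% and
95% CI coverage ≈ 94%. Full-pipeline interaction classification at
γ = 1 labels ~98–99% of replicates additive at α = 0.05: the Welch test
on dose-scale delta-method SEMs is *conservative* at these sample sizes
(type-I error ≈ 1% rather than 5%), erring against false synergy
claims, never toward them. At γ = 0.5 (strong synergy) the
supra-additive detection rate is ~51–55% — the fixed-dose design at
n = 24 per arm has modest power, which is why published studies of this
kind report conservative "additive" verdicts for all but large effects.

### What it does not show

The generator assumes exact probit linearity in log dose, parallel
curves, independent animals, and error-free dosing; real assays violate
all of these to unknown degrees. A fitted probit line applied to a
Loewe mixture is only locally linear in log varied-dose, so wide dose
spacing biases ED50_mix slightly low (visible at spacing 2 with a large
adjunct fraction); the calibration figures above include this effect.
Passing tests validate the statistical machinery, not the animal model.

## Reference fixtures

The bundled tables cover four ASMs (LCM, OXC, PGB, TPM) alone and with
imperatorin 25 or 50 mg/kg: ED50 ± SEM with probit-window n (summing to
232 animals), and brain concentrations mean ± SD (n = 8). The
intermediate pregabalin row is taken as the 25 mg/kg adjunct group,
consistent with every other drug block. The adjunct's own MES ED50 is
not part of these tables; demonstrations use a synthetic value of
110 ± 11 mg/kg, chosen because the tables' vehicle-to-mixture ED50
ratios imply, under additivity, an adjunct ED50 of roughly 85–155 mg/kg
(1 − ED50_mix/ED50_vehicle ≈ d/ED50_adjunct at d = 50). Fixture files
and docstrings label this value synthetic.

## Numerical and reporting conventions

* Probabilities clipped at 1e-12 inside the likelihood; ED50 extraction
  rejects |log₁₀ ED50| > 300 as degenerate.
* Report tables print ED50s to 2 decimals (1 for values > 100) and
  F/t to 3 decimals, round-half-even.
* Report bundles contain no timestamps; metadata records the package
  version, seed, α levels and SHA-256 digests of archived inputs, so a
  re-run on the archived inputs is bit-identical.
* Problem sizes in the validation suite — 2,000 replicates for
  recovery/calibration, 10,000 bootstrap resamples, 10⁵ Monte-Carlo
  propagation draws — were chosen as the smallest round numbers at
  which Monte-Carlo error is comfortably below the tolerances being
  checked.

## Known limitations

* Fixed-dose (subthreshold) isobolography only: no fixed-ratio designs,
  no dose-dependent additivity for non-parallel curves, no three-drug
  isoboles, no rendered figures (coordinates are exported instead).
* Probit link only — no logit or complementary log-log — and no
  per-animal covariates.
* Exact reproduction of published ED50s from raw counts is impossible
  when studies do not publish per-animal data; summary tables are
  treated as inputs, and the estimator is validated by oracle
  equivalence and simulation instead.
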