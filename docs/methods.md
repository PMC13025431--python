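# Methods

## Model

Lifetimes are modelled as two-parameter Rayleigh: a unit's failure time
X has density f(x | μ, σ) = ((x−μ)/σ²)·exp(−(x−μ)²/(2σ²)) on x ≥ μ, where
σ > 0 is a scale (time units) and μ ≥ 0 a threshold — the minimum possible
lifetime. The hazard (x−μ)/σ² is linear and increasing, which suits rapidly
ageing components. Under random censoring each unit also carries an
independent censoring time T ~ Rayleigh(μ, γ) with the *same* threshold; the
data are Y = min(X, T) and D = 1{X ≤ T}.

Three consequences of the construction drive everything else. Writing
β = 1/σ² + 1/γ²:

* Y is Rayleigh(μ, β^(−1/2)) — the observed times keep the two-parameter
  Rayleigh form;
* D ~ Bernoulli(p) with p = γ²/(σ²+γ²), independent of Y (transform to
  squared exceedances, which are exponential, and use the classical
  exponential min/indicator independence);
* the sample minimum y₍₁₎ is Rayleigh(μ, (nβ)^(−1/2)), so
  E[y₍₁₎] = μ + √(π/(2nβ)) and Var[y₍₁₎] = (4−π)/(2nβ).

A note on parameterisation: the field often writes "Rayleigh(μ, 1/β)" with a
variance-like second argument. We parameterise by the scale σ throughout
(`RayleighParams.sigma`), so the marginal of Y has scale β^(−1/2); this is
the convention under which the minimum-order-statistic moments above are
exactly recovered in simulation.

## Classical estimation

* **MLE.** The likelihood increases in μ up to the boundary, giving
  μ̂ = y₍₁₎ and, with w1 = Σdᵢ and w2 = Σ(yᵢ−μ̂)², the closed forms
  σ̂² = w2/(2w1), γ̂² = w2/(2(n−w1)). The identity σ̂²w1 = γ̂²(n−w1) holds by
  construction. w1 ∈ {0, n} makes one scale non-estimable and raises.
* **Profile MLE.** The log-likelihood contains Σlog(yᵢ−μ), which diverges
  to −∞ as μ → y₍₁₎, so the full likelihood actually has an interior optimum
  in μ. `mle_profile` concentrates the scales out exactly at each μ and
  maximises the resulting scalar profile by a 512-point grid scan plus
  bounded refinement (xatol 1e−12). Real-data fits use this mode; the
  boundary MLE is the default for the simulation tables, which are built
  around the y₍₁₎ theory. The two modes are a deliberate pair: the boundary
  form has clean closed-form moments, the interior form is the one a data
  analyst should report.
* **Variances & intervals.** The Fisher information for (σ, γ) is diagonal,
  I_σσ = 4nγ²/(σ²(σ²+γ²)), I_γγ symmetric, so the plug-in variances are
  V̂(σ̂) = w2/(8w1²), V̂(γ̂) = w2/(8(n−w1)²), and V̂(μ̂) = (4−π)w2/(4n²) from
  the minimum law. The μ interval uses the F(2, 2(n−1)) pivot based on
  w2* = Σ(yᵢ−y₍₁₎)²; scale intervals are normal-approximation, all lower
  bounds floored at 0 because the parameters are nonnegative. Empirical
  coverage of these intervals is *reported* by `interval_study`, not
  asserted at a nominal level: the asymptotic approximations undercover at
  the study's sample sizes.
* **Moments.** Equating d̄, ȳ, s²_y to E(D), E(Y), V(Y) gives unique
  closed-form estimates; requires 0 < d̄ < 1 and s²_y > 0.
* **LS / WLS.** The fitted marginal CDF is matched to plotting positions
  i/(n+1) in (weighted) least squares. The objective depends on (μ, β)
  only; the scale split uses the exact identity p = (1/σ²)/β with p̂ = d̄.
  Weights kᵢ = (n+1)²(n+2)/(i(n−i+1)) are reciprocal plotting-position
  variances. Optimisation is L-BFGS-B on (μ, log β) with five μ starts
  (ftol 1e−10); multi-start guards against the flat ridge at small β.

## Bayesian estimation

Conjugate inverse-gamma priors on σ² and γ² (hyperparameters (a1,b1),
(a2,b2); zeros give the non-informative limit) and a uniform prior for μ on
[0, y₍₁₎). The Gibbs sweep draws σ² and γ² from inverse-gamma full
conditionals with common scale b + S(μ)/2, S(μ) = Σ(yᵢ−μ)², then updates μ.

Two μ-samplers are implemented because the closed-form conditional CDF
F3(μ) = [(b + S(y₍₁₎)/2)/(b + S(μ)/2)]^(a1+a2+n−1) omits the Π(yᵢ−μ)
factor that the likelihood contains. The `printed` sampler inverts F3
analytically (truncated to [0, y₍₁₎) by drawing u ~ U(F3(0), 1)); it piles
μ up just below the sample minimum as n grows. The default `exact` sampler
draws from the full conditional ∝ Π(yᵢ−μ)·exp(−βS(μ)/2) by normalised
inverse-CDF on a fixed 2048-node grid over [0, y₍₁₎). Because the grid is
fixed per dataset, Σᵢlog(yᵢ−μₖ) and S(μₖ) are precomputed once and each
sweep costs a handful of length-2048 vector operations — this is what makes
replicated studies with the exact sampler affordable. Trapezoidal CDF
accumulation and linear interpolation bound the inversion error by the grid
spacing, which is ≤ y₍₁₎/2047 ≈ 3e−4 time units in the study settings.

Point estimates minimise generalised entropy loss (GELF)
L(θ, t) = (t/θ)^δ − δ·log(t/θ) − 1, whose Bayes rule is
θ* = (E[θ^(−δ)])^(−1/δ). δ < 0 penalises underestimation more. δ = −1 is
the posterior mean; the "squared-error" column of the study tables uses
δ = −2 (both sign conventions for the SELF label circulate; the CLI takes δ
explicitly). Scale estimates apply the transform to draws of σ and γ
(square roots of the sampled variances), and reliability functionals are
transformed per-draw. HPD intervals use the Chen–Shao shortest window over
sorted draws (K = ⌊(1−α)N⌋; ties to the smallest index). Convergence uses
arviz split-R̂ and bulk ESS; defaults M = 20 000, B = 5 000, 3 chains with
over-dispersed μ starts at 0.1/0.5/0.9 of y₍₁₎, flagging R̂ ≥ 1.1 or
ESS < 1000.

## Reliability functionals

MTSF = μ + σ√(π/2); hazard h(s) = (s−μ)/σ²; reliability
R(s) = exp(−(s−μ)²/(2σ²)); failure probability p = γ²/(σ²+γ²); expected
time on test ETT = μ + ∫₀^∞ [1 − (1−e^(−βt²/2))ⁿ] dt (the mean of the
largest observed time), with the complete-data variant replacing β by 1/σ².
The integral has no closed form and is evaluated by adaptive quadrature at
relative tolerance 1e−6 on [0, μ + 10·max(σ, γ)], with breakpoints placed
at the maximum's natural scale β^(−1/2)·(3 + √(2 log n)) so the adaptive
rule cannot overlook the mass when the nominal upper limit is much larger
than the support (the γ → ∞ limit). Default mission time is s = μ + MTSF/2.
Bayes estimates apply the GELF transform per posterior draw; ETT, which
costs one quadrature per draw, is evaluated on an evenly thinned subset of
at most 400 draws.

## Synthetic-data generator and study design

`sample_censored` draws (X, T) by inverse transform from 1−U and takes the
minimum — deliberately exercising the model construction rather than
sampling (Y, D) marginally. Because the uniforms do not depend on the
parameter values, studies run at two locations with a shared master seed
produce exactly translated samples, which the translation checks exploit.
Replicate r at sample size n uses the stream SeedSequence([seed, n, r]), so
any replicate is reproducible in isolation.

The study grid follows the published design: (μ, σ, γ) combinations such as
(0.5, 1, 1) … (5, 5, 3), n ∈ {20, 50, 100}, N = 5000 replications, AV/MSE
aggregation, with estimator failures (w1 ∈ {0, n}; vanishingly rare at
p = 0.5, n ≥ 20) excluded and counted. Informative priors set prior means
equal to the true parameters (b = (a−1)σ² etc.); the shape a = 3 is a free
sharpness choice, so those runs are validated qualitatively only, while the
fully specified non-informative setting is validated quantitatively.
Bayes-in-the-loop studies default to the scaled design N = 300 replicates
with single-chain M = 6000 / B = 1000 runs — chosen so a replicated study
completes in minutes on one core; at these sizes the Monte Carlo standard
error of the reported averages is ≈ 0.003, an order of magnitude below the
comparison tolerances.

What the generator does *not* emulate: real lifetime data with ties,
rounding, covariates, or censoring mechanisms that are informative or have
a different threshold than the failure law. Passing tests therefore
demonstrate correctness of the estimators under the model's own assumptions,
not robustness to their violation.

## Numerical choices and edge cases

* Ties X = T (measure zero) count as failures, matching D = 1{X ≤ T}.
* Inverse-transform sampling uses 1−U so log(0) is unreachable.
* All-equal samples give w2 = 0; the MLE returns zero scales with a
  `degenerate` flag rather than raising.
* GELF powers of nonpositive draws raise unless the power is a nonnegative
  integer (μ draws may touch 0; δ = −2 squares them safely).
* The K–S p-value uses the asymptotic Kolmogorov distribution of √n·D;
  no small-sample tables.
* The real-data fixture (69 carbon-fiber strength values) is treated as
  complete data; the model comparison asserts only the *direction* of the
  AIC/BIC ranking (two-parameter better), which is robust, not the printed
  fit statistics, which depend on optimizer interiors.

## Known limitations

* The boundary MLE's F-pivot interval for μ assumes the model holds exactly;
  under misspecification a bootstrap would be more defensible (not
  implemented).
* No Kaplan–Meier or other nonparametric comparison, no competing risks,
  no covariates, no importance-sampling posterior route — the Gibbs sampler
  is the single Bayesian computation path.
* Single-chain studies rely on the sampler's fast mixing (the μ conditional
  is drawn exactly, not by Metropolis steps); the diagnostics module is
  there to verify this on any concrete dataset.
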