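# Methods

## Model

Daily pain severity y_ij ∈ {1,…,5} for participant i on day j is modelled
as a cumulative (ordinal) probit regression with participant-level random
effects:

    z_ij = x_ij′β + w_ij′(γ + u_i) + u_i0 + B(t_ij)′s + ε_ij,   ε_ij ~ N(0,1)
    y_ij = c  ⇔  τ_{c−1} < z_ij ≤ τ_c,      τ_0 = −∞ < τ_1 < … < τ_4 < τ_5 = ∞

* **w_ij** — four scaled daily weather exposures: temperature per 1 °C,
  pressure per 10 mbar, relative humidity per 10 percentage points, wind
  speed per 1 m s⁻¹. Scaling fixes the reporting units of the coefficient
  table; each column is centered at the analysis-table mean (the constants
  are written to a sidecar file for exact invertibility).
* **γ** — population weather effects on the latent (probit) scale;
  **u_i ~ MVN(0, Σ)** — a correlated 5-vector (random intercept + four
  random weather slopes), the object of the heterogeneity analysis.
* **x_ij** — age (years), a female indicator, belief score (1–10), daily
  mood and exercise (1–5, entered as linear scores by default; a config
  switch expands them to category indicators).
* **B(t)** — natural cubic spline in days since the participant's first
  pain entry (default 5 columns; boundary knots at the observed range,
  interior knots at quantiles, columns mean-centered). It filters
  unmeasured time-varying influences; weather enters strictly linearly.

**Identification.** No global intercept; four free ordered cutpoints;
latent residual variance fixed at 1. Internally all fixed covariates are
centered at their analysis-table means, so cutpoints are defined at the
covariate means — a pure reparameterization that leaves slopes and all
reported summaries unchanged but removes the cutpoint/covariate-location
ridge from the posterior. Consequently the *location* of the cutpoints is
not comparable across parameterizations (recovery checks compare γ, Σ and
cutpoint *gaps*, which are invariant).

**Priors** ("noninformative", concretized): β, γ, s ~ N(0, 10²) each —
vague against a unit residual sd; improper flat prior on the ordered
cutpoint region; Σ ~ Inverse-Wishart(ν = 7, I₅), the conjugate choice with
ν = q + 2 (heavy-tailed, prior mean I₅). These are approximations in the
spirit of standard Bayesian mixed-model software defaults, not a claim
about any particular engine's exact priors. With hundreds of participants
the data dominate Σ; at a few dozen participants the IW prior inflates
small variance components noticeably (visible in the recovery tables).

## Gibbs sampler

Per iteration:

1. **Cutpoints** — random-walk Metropolis on (τ₁, log gaps) using the
   *marginal* ordinal likelihood (latent utilities integrated out); the
   utilities are redrawn immediately afterwards, making this a valid
   partially collapsed update. Three sub-steps per cycle; the proposal
   scale adapts during warmup toward ~35% acceptance (accepted range
   20–50%).
2. **Latent utilities** — z_ij from N(η_ij, 1) truncated to the category
   interval (Albert–Chib augmentation). The truncated-normal sampler uses
   inverse-CDF with tail reflection and is accurate for truncations far
   (>6 sd) into a tail.
3. **Coefficients (β, γ, s jointly)** — conjugate multivariate normal;
   the posterior-precision Cholesky factor is computed once (the fixed
   design never changes).
4. **Random effects** — each u_i from its conjugate normal full
   conditional, evaluated as batched 5×5 Cholesky solves across
   participants.
5. **Σ** — conjugate inverse-Wishart.
6. **Translation moves** — exact generalized-Gibbs draws along the three
   families of likelihood-invariant ridges: (τ location vs all random
   intercepts), (each γ_k vs the mean of its random slopes), and (each
   participant-level covariate coefficient vs the intercepts). Each shift
   leaves η unchanged, so its conditional under the priors is Gaussian in
   closed form. Without these moves the cutpoint location and the
   between-participant coefficients mix an order of magnitude more slowly;
   with them, 500 warmup + 500 kept iterations give max population R-hat
   ≈ 1.01–1.04 at the default study size.

Initialization is data-informed: cutpoints from probit-transformed
empirical cumulative category frequencies, coefficients at 0, Σ = 0.1·I
(a prior-draw strategy is available). Chains use independent numpy
bit-generator streams seeded by (seed, chain index); every run is exactly
reproducible. Draws of all blocks — including per-participant random
effects — are stored per chain; a rank-deficient design or a non-finite
latent draw aborts with a diagnostic naming the offending columns or
iteration.

**Diagnostics.** Rank-normalized split R-hat and bulk ESS (via arviz) for
every population-level scalar; a warn-don't-refuse gate at R-hat ≥ 1.05.
Posterior predictive checks simulate full replicate datasets at a thinned
subset of draws and compare the 5-category frequency distribution with its
central 95% predictive band.

## Summaries and classification

* **Population summary** — posterior mean and equal-tailed credible
  interval per γ_k, pooled across chains (equal-tailed, not HPD).
* **Marginal effect at the mean (MEM)** — with covariates centered and the
  spline mean-centered, the population-typical latent mean is 0; per draw,
  MEM = Φ(γ_k·δ − τ_{c−1}) − Φ(−τ_{c−1}) for threshold category c
  (default c = 3, "moderate or above") and δ = +1 scaled unit, averaged
  over draws (evaluation at posterior means is a config switch). Random
  effects are held at zero — the MEM describes the typical participant,
  not an average over the random-effect distribution.
* **Sensitivity labels** — per participant × parameter, the equal-tailed
  interval of the *total* slope γ_k + u_ik: entirely positive →
  high-value sensitive; entirely negative → low-value sensitive;
  straddling zero → undetermined. "Interval overlap" is with zero, per the
  cluster definitions; the forest plots show total slopes sorted by
  posterior median with the population mean as reference.
* **Diagnosis breakdown** — restricted to participants reporting exactly
  one condition, mapped to four groups (osteoarthritis; fibromyalgia/CWP;
  rheumatoid arthritis + ankylosing spondylitis/spondyloarthropathy as
  inflammatory arthritic pain; everything else as other chronic pain).
  No significance test is attempted across groups (deliberately — the
  subgroup counts are small).

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a test
fixture. It emulates:

* **Baselines** — 82.4% female, age ~ N(48.68, 13²) clipped to [18, 93],
  belief pmf with median 7 and IQR (6, 9), independent multi-label
  diagnoses at the published prevalences ("other/none" when no label
  drawn), plus small configurable rates of non-consent, incomplete
  baselines and single-day reporters to exercise the inclusion filter.
* **Follow-up and compliance** — per-participant durations are log-normal
  with median 106 days and IQR (53, 215) (σ = ln(215/53)/(2·z₀.₇₅)),
  capped by the study window; staggered entry over a 300-day recruitment
  window; reporting days thinned by a 0.65 compliance probability with the
  first and last day always reported.
* **Weather** — per station and variable: seasonal cosine mean + AR(1)
  daily deviations with cross-variable correlated innovations and small
  per-station offsets; humidity clipped to [0, 100], wind floored at 0.
  Hourly observations are a deterministic diurnal expansion whose daily
  means equal the daily values exactly, so nearest-station linkage
  reproduces the generating exposures to float precision. Participants sit
  at one home station (a configurable fraction spends one early week
  abroad, outside the UK bounding box, to exercise the exclusion rule).
  The processes are calibration devices, not meteorology.
* **Outcome** — the latent model above, with mood/exercise generated as
  ordinal covariates weakly dependent on the participant's random
  intercept (not on weather), so adjusting for them is exercised without
  confounding the weather effects.

**Calibration (fixed once).** Default latent effect sizes are the
*decisive* preset — γ = (−0.15, −0.15, 0.30, 0.15) per scaled unit with
random-effect sds (0.5, 0.15, 0.15, 0.40, 0.15) and equicorrelation 0.25 —
an order of magnitude above published population-scale estimates, so that
desk-scale recovery tests are conclusive. The default cutpoints
(−2.79, −1.09, 0.88, 2.40) were calibrated once against the realized
latent-scale distribution so the default cohort reports pain categories
2–3 on ≈70% of days with ≈8% in category 1 and ≈5% in category 5. A
`paper_scale_config()` preset carries the published coefficient magnitudes
for qualitative runs — effects that small are not recoverable at desk
scale, and no test pretends otherwise.

**What the generator does not emulate** — GPS jitter and missingness,
station network geometry, real UK meteorology, notification-driven
reporting patterns, informative dropout, or feedback from symptoms to
behaviour. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not robustness
to the messiness of real diary data.

## Data handling choices

* Days are calendar days; the daily exposure is the mean over all linked
  hours of that day, requiring ≥ 1 linked hour (configurable).
* Non-UK days are dropped via a configurable bounding box (default lat
  [49.8, 60.9], lon [−8.7, 1.8]).
* Nearest station by haversine distance (spherical Earth, R = 6371 km);
  ties break to the lowest station id for determinism.
* Inclusion: present in baselines, consented, baseline complete, ≥ 2
  distinct days of pain data.
* Missing mood/exercise on a reported day drops the row (complete-case);
  t = 0 at each participant's first pain entry, computed before the
  complete-case drop.
* Sex enters as a single female indicator ("other/unknown" → 0).

## Problem sizes and numerical choices

The desk-scale study conditions used throughout the tests and the
acceptance script: 300 participants (~21,000 participant-days) for
parameter recovery with 4 chains × (500 warmup + 500 kept), three
replicates, requiring ≥ 11 of 12 credible intervals to cover their
generating values and all population R-hats < 1.05; 50 participants with
≥ 60 reports each for classification recovery; 6,213 participants for
baseline-descriptor checks; a 20-participant smoke preset that runs the
full pipeline in seconds. Degenerate inputs are handled explicitly: too
few distinct times reduce the spline knots with a warning, constant chains
yield an R-hat NaN flag, empty cohorts and missing input files abort with
named diagnostics.

## Known limitations

* The sampler is single-machine, dense-matrix; cohorts beyond ~10⁴
  participants would need thinned random-effect storage.
* The IW(7, I₅) prior biases small variance components upward at small N;
  reporting both posterior means and intervals for sd components makes
  this visible rather than hiding it.
* MEM is defined at the population-typical participant (random effects at
  zero); population-averaged marginal effects would be smaller in absolute
  value and are not computed.
* Cutpoint locations are parameterization-dependent and should not be
  compared across software without matching covariate centering.
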