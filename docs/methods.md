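# Methods

## Quantification model

Standards are supplied in copies/µl and converted to copies/reaction via the
template volume (2.5 µl/reaction) before the ordinary-least-squares fit of
Cq on log10(copies/reaction); this is the only bridge consistent with
starting quantities being reported per reaction. Efficiency 10^(−1/slope)
outside [1.85, 2.05] or R² below 0.98 raises a QC warning, not an error —
published runs report observed ranges, not acceptance thresholds, so the
band is configurable. Cq values are accepted on (0, 40]; a reaction without
amplification within 40 cycles is a non-detect and enters all means as an
exact zero. Censoring is applied only later, at site level: a site whose 12
reactions all failed becomes a left-censored observation at the LOD
(220 copies/L), while a positive site mean below the LOD remains an
uncensored measured value. This two-stage treatment (zeros within sites,
censoring between sites) matches how the cited censored-data procedures
expect their input.

All concentrations are carried internally in copies/L; the µl-scale volumes
appear only in the conversion factor (V_water/E_extract)·D = 0.0025
copies/reaction per copy/L, under which the LOD corresponds to 0.55
copies/reaction.

## Censored likelihood and everything on top of it

One log-likelihood underlies the statistics:

ℓ(β, σ) = Σ_detects [log φ((ln x − x'β)/σ) − ln(σ x)]
        + Σ_nondetects log Φ((ln L − x'β)/σ)

with x'β = μ for the intercept-only model. Maximisation is over (β, ln σ)
by BFGS with analytic gradients, started from the detected-only least
squares/log-moments, gradient tolerance 1e-8, with one derivative-free
polish if BFGS reports failure. The fit is deterministic (no random
restarts). Degenerate inputs fail loudly: all-censored data (unbounded
likelihood), fewer than 3 observations, or identical uncensored values.
The ln(x) Jacobian term is included, so log-likelihoods (and AICc values)
are comparable with survival-package lognormal AFT fits; the test suite
cross-checks coefficients and log-likelihood against lifelines'
`LogNormalAFTFitter.fit_left_censoring` and the closed-form lognormal MLE.

* **Mean CI** — profile likelihood in θ = ln(mean) = μ + σ²/2: for fixed θ
  the likelihood is profiled over σ (bounded scalar minimisation), and the
  two roots of the deviance against the χ²₁ quantile are bracketed
  geometrically and solved by Brent's method. The method behind the
  original survey's printed limits is not stated anywhere; profile
  likelihood was chosen as reproducible and assumption-light, with a
  nonparametric percentile bootstrap behind `method="bootstrap"` as a
  cross-check. Simulated coverage at the survey's conditions (n = 70, ≈24%
  censoring) is ≈95% (acceptance suite).
* **Outlier screen** — a single pass flags values strictly outside
  mean ± 3·sd on the natural scale (both moments from the censored MLE);
  summary statistics are recomputed once after removal. Boundary values are
  kept (strict inequality).
* **Group comparison** — likelihood-ratio test between common-μ and
  per-group-μ models sharing one σ: the hypothesis concerns means of
  natural logs, so a common scale is the minimal alternative. A group with
  no detects triggers a warning (its mean is weakly identified), not an
  error. Simulated type-I error at the survey's basin sizes (9/21/20/20)
  is ≈0.06 at α = 0.05 — the mild liberality expected of an asymptotic LRT
  at n = 70.
* **Regression** — lognormal AFT with optional per-covariate log or
  cube-root transforms; rows with missing covariates are dropped (counted,
  warned) so all models in a set share rows and AICc is comparable.
  Collinearity is screened two ways: per-covariate VIF (via statsmodels)
  for reporting, and pairwise VIF 1/(1−r²) against the configured threshold
  (default 5) to forbid pairs from co-occurring in any model.
* **Model selection** — all covariate subsets avoiding forbidden pairs plus
  the null model; AICc = −2ℓ + 2p + 2p(p+1)/(n−p−1) with p counted as
  coefficients (incl. intercept) + 1 for σ, so the null model has p = 2.
  Published model tables sometimes count parameters differently (df
  conventions vary and are not always internally consistent); this
  package's convention is fixed as stated and not adjusted per table. An
  explicit model-list mode reproduces externally specified tables. No
  multiplicity correction is applied across the table; weights are
  descriptive.
* **Shapiro–Francia** — W′ is the squared correlation of the order
  statistics with Blom scores Φ⁻¹((i−3/8)/(n+1/4)); the p-value uses
  Royston's normal approximation for ln(1−W′) (5 ≤ n ≤ 5000). Verified to
  10 decimals against R's `nortest::sf.test`.

## Mass balance

S = (k + R/V)·C·V is used in full everywhere; the lake's R/V ≈ 2.8×10⁻⁴/day
is negligible against k = 0.877/day (< 0.1% effect, asserted by a test) but
no simplified branch exists. The laboratory chain divides the raw rate by
the tank throughflow (3,900 copies/kg/s × 86,400 s/day ÷ 456 L/day =
7.39×10⁵ copies/L): "corrected for flow" rates are concentration × flow, so
recovering the concentration is a division even where source texts phrase it
loosely as multiplication. All chain arithmetic is full precision; rounding
to 3 significant figures happens only at report time. Constants (k,
geometry, calibration) live in the config, not in code, so the model
transfers to other systems. Uncertainty in k and in the per-kg rate is not
propagated — only the concentration CI is — which is why the estimate is
called *relative* biomass.

## Synthetic surveys

The generator works backwards through the same mass balance: a true biomass
(default 4.83×10⁶ kg) implies a true mean concentration (≈1688 copies/L).
Sites are zero-inflated lognormal: structurally fish-free with probability
0.18, otherwise lognormal with the grand mean preserved and log-sd 1.525.
These two defaults were set together so that (a) simulated surveys average
≈24% non-detect sites and (b) the site-level sd/mean ratio is ≈3.4 — the
dispersion the target survey observed; a single lognormal cannot produce
both the non-detect share and the long right tail at once. Water replicates
get lognormal noise with CV 0.30, a free parameter (no published
between-replicate variance exists to calibrate it; it is reported in all
test output via the design object).

Detection is mechanistic per reaction: expected copies λ = 0.0025·C,
realised copies Poisson(λ), each copy amplifying with probability
a = ln 20 / (12 × 0.55) ≈ 0.454 — calibrated analytically so a site at the
LOD, with 12 reactions, is detected with probability 0.95, matching the
LOD's definition. (A pure Poisson single-copy model cannot make 0.55
copies/reaction a 95% limit at any per-replicate interpretation; the
site-level calibration is the one the LOD's empirical definition supports.)
Amplifying reactions get Cq from the standard curve at the detected copy
number plus Gaussian noise (sd 0.15 cycles). Standards are modelled as
precisely pipetted: their Cq is the forward prediction at a·q plus the same
Gaussian noise, without single-molecule sampling noise. The fitted curve
thereby absorbs the factor a exactly as an empirical curve does on a real
plate, keeping back-calculated sample quantities unbiased (verified: mean
recovery within ~0.1% at 1000 copies/L) and keeping simulated efficiencies
inside the observed 1.91–2.00 band.

Covariates are drawn inside the target survey's observed min–max envelopes;
TSM and chl-a are bivariate normal on the log scale with correlation 0.9
(the collinear pair), others independent; a few cells are blanked to
emulate incomplete satellite retrievals. By default covariates are
independent of concentration, so regression nulls hold by construction; a
`covariate_beta` vector enables power studies.

What the generator does **not** emulate: spatial autocorrelation and
hydrodynamic transport (sites are exchangeable draws), carcass point
sources, temperature-dependent decay, inhibition (IPC rows are emitted
clean), and contamination. Passing tests therefore demonstrate calibration
of the statistical machinery under the assumed sampling model, not
robustness to those field realities.

One global seed drives a spawned per-survey seed sequence, so replicate
surveys are independent yet byte-reproducible.

## Problem sizes and numerical checks

Simulation-based checks use 2000 replicates for the group-test type-I error
and the Shapiro–Francia null rate, 1000 for mean-CI coverage, and 500 full
synthetic surveys for end-to-end biomass recovery (coverage in [0.90, 0.99],
median bias < 10%); these sizes give Monte-Carlo standard errors of ~0.5–1
percentage point on the rates being checked. The brute-force grid oracle
for the censored MLE refines a coarse grid to 10⁻³ resolution and agrees
with the optimiser to 10⁻². Note that with 70 independent sites the
*per-survey* non-detect count is binomial with sd ≈ 4 sites, so individual
surveys legitimately range from ~13% to ~36% non-detects; calibration is
asserted on the across-survey mean.

## Known limitations

- The biomass estimate inherits every caveat of the transferability of k
  and the laboratory shedding rate; only concentration uncertainty is
  propagated.
- The censored-lognormal mean is mildly model-misspecified under the
  zero-inflated truth the simulator (deliberately) generates; the
  end-to-end acceptance check shows the resulting bias stays within a few
  percent at the default design, but it grows with the structural-zero
  share.
- Profile CIs assume the lognormal shape; for strongly non-lognormal data
  use the bootstrap method and expect wider intervals.
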