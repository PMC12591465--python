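# edna-biomass

Stock assessment of bigheaded carps (silver carp, bighead carp and their
hybrids) in a large shallow lake from an environmental-DNA survey. The
package turns raw qPCR plate data into site-level eDNA concentrations,
summarises them with statistics built for left-censored data, and converts
the mean concentration into a **relative biomass** estimate through a
shedding/decay mass balance calibrated against a laboratory tank experiment
with known fish biomass. A synthetic-survey generator with known truth makes
every stage testable end to end without any field data.

It is written for fisheries and molecular-ecology researchers who have qPCR
plate exports (Cq values) or a per-site concentration table and want a
reproducible, testable route from those to a biomass figure with honest
confidence bounds.

## The model

**Quantification.** Each plate carries a tenfold standard dilution series;
the standard curve Cq = b + m·log10(q) gives amplification efficiency
E = 10^(−1/m) and back-calculates each reaction's starting quantity
SQ = 10^((Cq−b)/m) (copies/reaction). Concentration in the sampled water is
C = (SQ/D)·E_x/V with D the template volume per reaction (2.5 µl), E_x the
extract eluate volume (50 µl) and V the water volume sampled (0.05 L).
Non-detect reactions enter as zeros; a site's value is the mean of its
4 water × 3 technical replicates.

**Censored statistics.** Non-detect sites are known only to lie below the
limit of detection (LOD, 220 copies/L), so site concentrations are modelled
as lognormal with left censoring: detects contribute density terms,
non-detects contribute Φ((ln L − μ)/σ) terms to the likelihood. On this one
likelihood the package builds the MLE summary (mean e^{μ+σ²/2}, median e^μ,
sd), a profile-likelihood CI for the mean, a ±3·sd outlier screen, a
likelihood-ratio test of equal basin means, and lognormal
accelerated-failure-time regression on environmental covariates with
VIF-based collinearity screening, all-subsets enumeration, AICc ranking with
Akaike weights, and Shapiro–Francia residual normality tests.

**Mass balance.** At steady state, S = (k + R/V)·C·V links total shedding S
(copies/day) to concentration C via decay rate k (0.877/day), outflow R and
volume V. Applied to a calibration tank (3,900 copies/kg/s through 456 L/day
and 379 L) it yields a per-kg shedding rate of 5.83 × 10⁸ copies/kg/day;
applied to the lake (V = 1.9 × 10¹² L, R = 5.4 × 10⁸ L/day) and divided by
the per-kg rate it converts the mean concentration and its confidence limits
into biomass (kg → tonnes → kg/ha over the 596 km² surface).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
survey (outputs under `results/`):

```bash
python analysis/01_simulate_survey.py
python analysis/02_quantify_plates.py
python analysis/03_summary_statistics.py
python analysis/04_covariate_models.py
python analysis/05_biomass_estimate.py
```

which prints, for the default seed:

```
true biomass        : 4.83e+06 kg
true mean conc      : 1688.1 copies/L
non-detect sites    : 18/70
...
efficiency range    : 1.983 – 2.018
R^2 range           : 0.9986 – 0.9997
...
mean (95% CI)       : 2347.0 (1287.7 – 5748.6) copies/L
basin test          : chi2=3.12, df=3, p=0.37
...
biomass             : 6720 t (95% CI 3680 – 16400 t)
areal density       : 113.0 kg/ha
simulator truth     : 4830 t (inside the CI)
```

Reading: 18 of 70 sites had no amplification in any of their 12 reactions
and enter the fit as left-censored values; basins do not differ
significantly; the estimate (6,720 t) sits above the known truth (4,830 t)
for this particular draw — between-site patchiness (sd/mean ≈ 3.4) makes
single-survey estimates noisy, which is exactly why the CI is wide — and the
95% interval covers the truth. Across 500 replicate surveys the median bias
is a few percent and coverage ≈ 95–98% (`end_to_end_recovery`).

The same stages are available as CLI subcommands
(`edna-biomass simulate|quantify|summarize|compare-basins|regress|biomass|pipeline`)
for use on real plate or site CSVs.

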