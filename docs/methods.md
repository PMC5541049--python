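# Methods

## Evidence model

Each literature finding is one record: a pathogen, one of 11 climate-driver
sets, and a signed strength score on a semi-quantitative rubric grid
(default absolute values {5, 20, 40, 60, 80}; negative values encode
contradicting evidence).  Records for the same (pathogen, driver) pair are
reduced to their **median** — for even record counts the mean of the two
middle order statistics, so midpoints such as 22.5 occur.  *Positive
evidence* is a strictly positive median: a median of exactly zero (e.g. +60
and −60) counts as no positive evidence.  Pairs with no records at all are
kept distinct from pairs with non-positive medians in outputs (absent vs
≤ 0), but both mean "not sensitive" downstream.

Records are unweighted: one published finding contributes one score,
regardless of source quality or recency.  The record schema reserves a
free-text `tag` (e.g. direct vs indirect driver action) that no computation
consumes.

The 11 driver sets partition into 7 primary drivers (direct climate
variables: climate change, oscillations, extreme weather events, moisture,
rainfall, temperature, wind) and 4 secondary proxies (altitude, vegetation,
particulate matter, salinity).  The vocabulary ships as a packaged CSV and
is overridable via YAML; labels are matched case-insensitively after
trimming, tolerating a trailing plural "s" and a few common synonyms
("particle matter", "climate oscillations").  The underlying ~190 raw
climate search terms are represented only at the 11-set level, since every
statistic operates on the sets.

## Cohort statistics

A pathogen is *sensitive* when it has ≥ 1 positive driver; this definition
is used identically in every breakdown.  Summaries store only integer
counts (driver-count histogram, per-driver frequencies, unordered-pair
co-occurrence counts); percentages are derived on demand and rounded to one
decimal only for display, to avoid compounding rounding.  Taxon breakdowns
partition the cohort; route breakdowns are multi-membership (a pathogen
with three routes appears in three route summaries), so route totals sum to
the total number of (pathogen, route) incidences, not the cohort size.

## Inference

- **χ² on 2×2 tables** is Pearson's without continuity correction, df = 1,
  with effect size φ = √(χ²/N).  Omitting the Yates correction is what makes
  φ equal to the absolute Pearson correlation of the two binary indicators;
  both identities are tested.
- **Odds ratios** are cross products ad/bc with 95% Woolf intervals
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  Zero cells raise an error unless
  the Haldane–Anscombe +0.5 correction is explicitly enabled.
- **Logistic regression** is fitted by IRLS (via statsmodels GLM/binomial),
  convergence when the largest coefficient change is below 1e−8, at most
  100 iterations.  Adjusted odds ratios are e^β with Wald 95% CIs.
  Quasi-separation (a fitted probability within 1e−8 of 0 or 1) emits a
  warning and flags the affected results rather than failing, since the
  point estimates of the remaining terms are still interpretable;
  non-convergence without separation is an error.  Missing host class is
  handled by listwise deletion.
- **H-index quartiles** use the empirical 25/50/75 percentiles (linear
  interpolation) as boundaries; a value equal to a boundary stays in the
  lower quartile, and all-tied inputs collapse to quartile 1.  Quartile
  predictors expand to three indicators against a first-quartile baseline.
- **Multivariable selection** enters the univariably significant
  (p < 0.05) predictors and backward-drops the weakest term while any
  p ≥ 0.05 remains.  p-values in [0.05, 0.10) are flagged as borderline.
- No Fisher exact tests, no Firth correction, and no multiple-testing
  adjustment are applied.

The model battery (`stats.run_paper_models`) runs, on one cohort: the
zoonotic × any-driver 2×2 (χ², φ, and ORs of zoonotic vs human-only and vs
animal-only pathogens); univariable logistic models of zoonotic status on
direct-contact, waterborne and foodborne transmission, then the
backward-selected multivariable model; two emergence models (emerging on
rainfall evidence + H-index quartiles, and on climate-change evidence +
H-index quartiles — fitted separately); the emerging × any-driver 2×2; the
correlation of route count with driver count; and the OLS regression of
country count on driver count with its F(1, n−2) test.

## Burden attribution

The packaged fixture is a 25-disease extract of the 2010 GBD study:
all-ages DALYs in thousands, the climate drivers with positive median
evidence per disease (as short codes), the matching medians, and the taxon
of the causative pathogen(s).  Where a disease has two reviewed constituent
pathogens a driver cell carries two "+"-joined medians; the disease counts
as sensitive to a driver if **any** constituent median is positive, and the
disease is counted once.  Classification is `primary` if any positive
driver is primary-class, `secondary_only` if sensitive without a primary
driver, else `none`.  DALY shares are computed on unrounded sums over the
25-disease total; the relative DALY impact of a disease is its DALYs
divided by the all-cause total of 2,490,385 thousand, reported in percent
and rounded to two decimals only for display.

## Synthetic-data generator

The generator emulates a systematically reviewed cohort: default 157
pathogens across five taxa (mix weighted towards bacteria and viruses, with
single-digit protozoa/helminth counts), eight transmission routes drawn
independently with the prevalences of the European high-impact cohort
(direct contact 81/157 … soilborne 5/157; a pathogen with no draw is forced
one propensity-weighted route).

Latent truth is binary per (pathogen, driver): sensitive with probability
`driver_base_rate × boost`, where the boost is the maximum over the
pathogen's routes (defaults 4.0 vector-borne > 2.8 soilborne > 2.5
waterborne > 2.0 foodborne > … > 0.5 sexual contact, mirroring the observed
route ordering).  The default base rate 0.052 puts the closed-form expected
sensitive share (`expected_fraction_sensitive`, which marginalises exactly
over the route process) at ≈ 0.63 of the roster, matching a cohort in which
99 of 157 pathogens are climate sensitive.

Observed evidence is noisy around the latent truth: sensitive pairs attract
max(1, Poisson(3)) records with 90% positive scores; insensitive pairs
attract records with probability 0.08 and mostly weak/negative scores, so
observed medians can disagree with latent truth and the strict-positivity
rule is genuinely stressed.  The zoonotic flag is drawn from a logistic
model whose log-odds differ by ln(`zoonotic_sensitivity_or`) (default 6.0)
between latently sensitive and insensitive pathogens; host class is
otherwise split evenly between human-only and animal-only, with a ~1/157
chance of an unknown host class.  Emergence is independent by default
(rate 0.25); H-indices are negative-binomial (mean 30, dispersion 2);
country counts are a linear function of the latent driver count (slope 1.1)
plus Gaussian noise, clipped to [1, 51].  All randomness flows from one
`numpy` generator seeded by the config; the same seed yields byte-identical
CSVs.  The attribute table carries `latent_sensitive` / `latent_n_drivers`
truth columns for parameter-recovery checks; pipeline readers ignore them.

What the generator does **not** model: publication behaviour (evidence
volume is independent of effect direction), correlations between drivers,
citation dynamics behind the H-index, and any real geography.  Passing
tests therefore demonstrate that the pipeline recovers the effects it is
fed under idealised sampling, not that the published effect sizes are
correct.

## Verification strategy and problem sizes

Unit tests check every statistic against an independent closed-form or
brute-force oracle (sort-and-pick median on random grid multisets;
Σ(O−E)²/E for χ²; cov/var for the OLS slope; the saturated-model identity
AOR = ad/bc for single-predictor logistic fits).  Calibration tests use 200
seeded replicates: with a configured zoonotic-sensitivity OR of 3 at 5,000
pathogens the Wald CI covers the truth in ≥ 90% of replicates, and with all
effects switched off every monitored CI covers its null in ≥ 90% of
replicates at the default cohort size of 157.  These replicate counts and
sizes keep the full suite under a minute while leaving Monte-Carlo error
well below the 90% acceptance threshold (binomial SE ≈ 1.5% at 200
replicates).

## Known limitations

- Wald intervals undercover slightly for sparse cells; no profile-likelihood
  or exact alternatives are offered in this version.
- The backward-selection rule is one of several defensible multivariable
  strategies; results for correlated predictors depend on it.
- Secondary drivers (altitude especially) can proxy non-climate factors;
  the package reports them separately but cannot disentangle them.
- Real-data reproduction of the cohort-level statistics requires the
  original per-pathogen evidence tables, which are not redistributed here;
  the packaged burden fixture is the only published-data surface.
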