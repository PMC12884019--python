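# Methods

## The estimand and the estimation chain

The package estimates, for each burden year, the fraction of cancer cases
and deaths that would not occur if the population's intake of a dietary
factor were at its optimal level — the population-attributable fraction
(PAF) — and the corresponding attributable cases (AC).  Estimation runs in
five stages:

1. **Exposure.**  Single-day intake records are summarised per factor, sex
   and survey year.  Means and exposure prevalences are directly
   age-standardized to fixed standard-population weights (the convex
   combination Σ w_g m_g over 5-year age groups 20–24 … 85+).  Exposure is
   intake above the optimal upper bound for risk-increasing factors and
   below the lower bound for protective ones.  Years without a survey wave
   are bridged linearly: OLS back-cast to 2000, interpolation between
   waves, OLS forecast beyond the last wave, with prevalence clamped to
   [0, 1] and intakes to ≥ 0.  Standardizing the prevalence with the same
   weights as the means keeps the two internally consistent.
2. **Relative risks.**  Study-level dose-response RRs (with 95% CIs and
   their own unit increments) are rescaled to the factor's target unit
   under the log-linear assumption (β′ = β·u/u_s) and pooled with the
   DerSimonian–Laird moment estimator.  Heterogeneous sets (Cochran Q
   p < 0.05 or I² > 50%) are pruned by iterative leave-one-out removal of
   the study whose exclusion most reduces I², stopping at k = 2; removals
   are recorded in the pooled result.  This keeps a usable pooled estimate
   for every factor–site link while honouring the screening rule.
3. **PAF.**  Per factor–site–sex–year–outcome cell, the dose-modified
   Levin formula PAF = x/(x+1) with x = P(e^{β·dose} − 1).  Exposure is
   lagged by the latency L: burden year Y uses the exposure state of
   Y − L.  For protective factors the risk-direction β is the negated
   pooled coefficient applied to the intake deficit, which keeps x ≥ 0; a
   cell where noise drives the oriented β below zero yields a small
   negative PAF rather than an error (x ≤ −1 is rejected as a sign bug).
4. **Aggregation.**  AC = PAF × count per cell; groups (factor, direction
   group, all-dietary, site, all-cancers) sum member ACs and divide by the
   group denominator.  Sex-combined rows sum sex-specific ACs over the
   combined denominator — PAFs are never averaged.  When several factors
   act on one site the ACs add (independence assumption) and are capped at
   the site count with a logged warning.
5. **Uncertainty.**  Monte Carlo percentile intervals: per repetition each
   pooled β is redrawn from Normal(β, se) and each prevalence from
   Beta(Pn, (1−P)n) with n the stratum's survey size; the whole cell
   vector is re-evaluated and re-aggregated jointly, so group intervals
   are coherent with their members.  2.5th/97.5th percentiles of 10,000
   repetitions form the 95% CI.

Future-year burden (2025/2030) uses the identical machinery with pooled
RRs held fixed; denominators come from externally supplied projected
counts when available, otherwise from a log-linear trend in historical
rates applied to the projected population.  At the default 15-year latency
the projection years consume the already-observed 2010/2015 exposure, so
no exposure forecasting is required.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| latency | 15 (alt. 10, 20) | years | diet–cancer associations are long-term; the lag maps burden years 2015–2030 onto exposure years 2000–2015 |
| optimal range, fiber | 19–28 | g/day | GBD 2017 TMREL |
| optimal range, veg/fruit | 490–730 | g/day | GBD 2017 TMREL |
| optimal bound, red meat | 27 | g/day | GBD 2017 TMREL upper end |
| optimal bound, processed meat | 4 | g/day | GBD 2017 TMREL upper end |
| optimal bound, salted vegetables | 10 | g/day | no TMREL published; typical global average intake |
| optimal bound, salted fish | 5 | g/day | no TMREL published; typical global average intake |
| unit increments | 120 / 50 / 40 / 20 / 10 / 100 | g/day | the increments the dose-response literature reports on (red meat, processed meat, salted vegetables, salted fish, fiber, veg/fruit) |
| `dose_basis` | `gap` | — | see below |
| `rr_region` | `korean` | — | domestic pooled RRs; `asian`/`global` reproduce the sensitivity analysis |
| `mc.reps` | 10,000 | — | percentile CI noise ≈ 0.02 PAF-percentage points at typical effect sizes |
| `mc.vary` | `rr_and_prevalence` | — | which inputs are perturbed per repetition |

**Dose basis.**  Two readings of "dose" are implemented.  The default
`gap` uses the age-standardized mean distance between intake and the
optimal bound among the exposed, which makes the PAF vanish smoothly as
the population approaches optimal intake.  The literal `mean` mode uses
the standardized mean intake among the exposed; it assigns excess risk
even to intake just beyond (or at) the bound and is retained for
sensitivity.  Published burden studies are often ambiguous on this point;
the gap reading mirrors how counterfactual-exposure frameworks treat
distance to the TMREL.  Either way the dose is divided by the factor's
unit increment before entering e^{β·dose}.

**Protective factors.**  The Levin formula needs a risk-direction β.  The
exposed group for a protective factor is "intake below the optimal low
bound" and β_used = −β_pooled = log(1/RR_protective), applied to the
deficit dose.  This is a modelling convention (the counterfactual is
raising low consumers to the bound), consistent with how
counterfactual-exposure frameworks handle protective exposures.

## What the synthetic generator emulates — and what it does not

`dietburden.synthetic` produces the three input tables with known ground
truth.  Intakes are zero-inflated log-normal per factor, sex and year:
right-skewed, strictly positive continuous part, a point mass at zero for
episodically eaten foods (processed meat, salted fish), linear secular
trends in the continuous-part mean and optionally in the zero mass.
Default parameters are anchored once to the Korean dietary landscape of
2000–2015 (salted vegetables ≈ 146 g/day in 2005 and declining; red meat
rising from ≈ 72/46 g/day male/female; processed meat rare but spreading;
fiber ≈ 21–24 g/day; non-starchy vegetables and fruits ≈ 340 g/day versus
a 490–730 optimal range).  Counts are Poisson(rate × population) with
deaths obtained by binomial thinning of the incident draw — this preserves
the Poisson marginal for deaths while guaranteeing deaths ≤ incidence in
every stratum, which independent draws would not.  Study effects follow
the random-effects model β_i ~ N(β_true, τ² + se_i²), with every third
study reported on double the target unit so rescaling is exercised.

Not emulated: survey weights and household clustering, multi-day recall
correction, within-person day-to-day variance (a single draw per person
plays the role of the single recall day), age gradients in intake, and
cohort effects beyond the linear trend.  Passing tests therefore
demonstrate that the estimation chain recovers the truth of *this*
generative family; they do not validate the single-recall exposure model
against real dietary measurement error, which is a known limitation of the
study design itself.

## Numerical choices

- 95% CIs of study effects are converted to SEs with the conventional
  z = 1.96 (se = (log ci_high − log ci_low)/3.92); the same constant is
  used when reconstructing CIs, so conversion round-trips exactly.
- DL with k = 1 passes the single study through (τ² = 0, Q = 0) with a
  warning instead of failing, so a sparse evidence base still yields a PAF.
- I² = max(0, 100(Q − (k−1))/Q), zero when Q = 0; τ² is floored at 0.
- Leave-one-out screening breaks ties by (remaining I², remaining Q,
  study id) for determinism.
- Trend fitting is ordinary least squares on calendar year
  (scipy.stats.linregress); a single observed year is an error, a constant
  series yields slope 0.  Extrapolation beyond the observed range (e.g.
  the 2000 back-cast, or factors with short survey series such as fiber)
  is flagged in the output and logged.
- Beta prevalence sampling degenerates to a fixed P when P ∈ {0, 1} or no
  effective sample size is available.
- All generators and the Monte Carlo engine derive independent
  deterministic substreams from one root seed (numpy SeedSequence-style
  `default_rng([seed, stream_id])`); same seed ⇒ byte-identical outputs.
- PAFs are reported as percentages to 2 decimals and ACs rounded half-up
  to integers at reporting time only; full precision is carried internally
  and the AC/denominator = PAF identity is asserted on every written row.

## Problem sizes used in the test and acceptance runs

Statistical tests run at sizes where their tolerances are principled:
law-of-large-numbers and tail-probability checks at 50,000–100,000
records (3 binomial/sampling SEs), pooled-β recovery at k = 50 studies
(3 pooled SEs), pipeline recovery at 100,000 records and k = 20 studies,
interval coverage at 500 simulated datasets × 1,000 repetitions, and the
percentile-oracle comparison at 10⁶ repetitions with a 3-SE percentile
tolerance (≈ 0.06 PAF-percentage points).  The default multi-factor
demonstration world uses 2,000–8,000 persons per survey wave.

## Known limitations

- Single-day recall misclassification is not corrected; prevalence and
  dose inherit its upward dispersion bias.
- Cross-factor independence: overlapping attributable cases are summed,
  which can overstate site totals (hence the cap-and-warn at site counts).
- A uniform latency across cancer sites ignores site-specific lags.
- The rate-trend count projection is a convenience fallback, not a
  demographic projection; supply national projected counts when available.
- Dose uncertainty is not propagated (prevalence and RR dominate; no dose
  SE is available from a single survey summary).
- REML/Paule–Mandel estimators and non-linear (spline) dose-response are
  out of scope; the per-unit log-linear β is the modelling unit.
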