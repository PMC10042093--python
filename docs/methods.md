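# Methods

## Scope

The package implements the external-validation-and-recalibration analysis
of a non-laboratory 10-year cardiovascular risk model: a synthetic
multi-region cohort simulator, a risk engine with per-sex coronary and
stroke submodels, stratum-wise recalibration, censoring-aware validation
statistics, and a pipeline that runs the two-component design (universal
model validated before and after per-region recalibration). Real cohort
linkage, ICD adjudication and laboratory-based model variants are out of
scope.

## Risk model

Each of the four submodels (2 sexes × 2 subtypes) is a Cox-chart score:
`lp = Σ β_k (x_k − c_k)` over age (years), current smoking (0/1),
systolic blood pressure (mmHg) and body mass index (kg/m²), with optional
age-interaction terms, and a reference 10-year risk `p_ref ∈ (0,1)` at the
centring point. The risk transform is on the survival scale,
`p = 1 − (1 − p_ref)^exp(lp)`, so `lp = 0` returns `p_ref` exactly and
recalibration is exact on the cumulative-hazard scale. Centring defaults
(age 60, SBP 120 mmHg, BMI 25 kg/m²) are stored in the model file and are
part of the model, not the code.

Total cardiovascular risk combines the subtype risks as a complement
product, `1 − (1 − p_cor)(1 − p_str)` — the unique symmetric rule that
reduces to each submodel when the other risk is zero and respects the
independent-subtype survival interpretation. A capped-sum alternative is
available (`combine_rule="capped_sum"`) for sensitivity.

Coefficients are data: models are JSON files. The shipped default model
is illustrative — plausible magnitudes for a non-laboratory chart, with
reference risks deliberately below a high-incidence target population so
that the recalibration machinery is exercised. No number in the default
file is used as a test oracle; all tests use hand-set coefficients.

## Recalibration

For stratum *s* (region × sex × age band; 10-year bands 40–49 … 70–79 by
default, configurable) and subtype:

- `r̄_s` = arithmetic mean of `exp(lp)` over stratum members. Arithmetic
  rather than geometric, so that the stratum's expected events match the
  sum of relative risks; the geometric option is behind a flag.
- `p̄_s` = expected 10-year risk, either loaded from an external parameter
  table (CSV schema: region, sex, age_lo, age_hi, subtype, expected_risk,
  mean_rr, provenance) or estimated empirically as the Kaplan–Meier
  10-year risk of that subtype within the stratum — the same KM
  implementation used for validation, so the two cannot drift.
- Each participant then gets `p′ = 1 − (1 − p̄_s)^(exp(lp)/r̄_s)`.

This cumulative-hazard scaling is monotone in `lp`, so risk ordering
within a stratum is preserved exactly *per subtype*. The combined total
risk is a complement product of two differently-exponentiated transforms,
so the total ordering is only near-preserved across participants whose
coronary and stroke predictors disagree; empirically the within-region C
on total risk moves by well under 0.01.

Strata with zero observed events get the continuity-correction floor
`p̄_s = 0.5 / n_s` with a warning, keeping the power transform defined.
When the study uses a narrower outcome-definition variant, the empirical
parameters are estimated under the same variant (subtype event thinning),
so recalibration targets the outcome actually being validated.

The "super-region" mode (external table whose single region label is not
a cohort region) broadcasts one stratum scheme over all participants —
the "model for East Asia" style of recalibration — and reuses the exact
same transform; per-region mode only changes the stratum scheme.

## Validation statistics

**Harrell's C.** All pairs are enumerated block-vectorised (O(n²) with
bounded memory). A pair is comparable when one member has an observed
event strictly before the other's event-or-censoring time, or at the same
time as the other's censoring; both-event time ties are not comparable;
risk ties score ½ (this makes the all-tied case exactly 0.5). The default
CI uses the Hájek-projection variance of the ratio of the two underlying
U-statistics (per-subject concordance and comparability counts); a seeded
subject-bootstrap (200 resamples) is the alternative. The implementation
is checked exactly against a brute-force pure-Python pair enumeration.

**Kaplan–Meier risk.** Product-limit estimate at `t0` with events at a
time preceding censorings at that time; variance by Greenwood's formula.
With no censoring before `t0` it reduces to the empirical proportion.

**Calibration table.** Equal-size quantile groups of predicted risk
(deciles by default), ties broken by stable input order; per-group
observed risk and variance from the KM estimator.

**P/O ratio.** `Σ p_i / (n · KM risk at t0)` — predicted cases over
censoring-adjusted observed cases; 1 is ideal, below 1 underestimation.

**Nam–D'Agostino χ².** `Σ_d (o_d − p̄_d)² / v_d` with Greenwood `v_d`.
Groups with zero events (zero variance) are merged into the adjacent
lower-risk group first; the merge count is reported. Because no parameter
is refit in external validation, the G group summaries are independent
and the statistic is referred to χ² with **df = G** (the default); the
Hosmer–Lemeshow-style `df = G − 1` convention is available as
`df_mode="groups_minus_1"` but is anti-conservative here (null simulation:
statistic mean ≈ G, variance ≈ 2G; rejection at α = 0.05 is ≈ 0.05 with
df = G and ≈ 0.08 with df = G − 1). The χ² reference additionally needs
adequate events per group (≈ 20+); with very rare lowest-decile risks the
lowest group's z-score is heavy-tailed and the test over-rejects under
any df — the type-I-error simulation in the test suite therefore draws
true risks from Beta(4, 16) (mean 0.20, ≈ 30+ events per decile at
n = 5000).

**Pooling.** Per-region C indices are pooled by DerSimonian–Laird
random-effects meta-analysis (via `statsmodels`), with the moment
estimate of τ² truncated at zero (weights then reduce to fixed-effect).

## Synthetic cohort generator

The generator emulates a prospective multi-region cohort of adults aged
40–79:

- **Regions** (10 by default, 5 urban/5 rural) differ in smoking
  prevalence (women 0.2–10.2%, men 39–65%), SBP and BMI means, and
  baseline-hazard multipliers (coronary ×0.6–1.6, stroke ×0.45–3.0 —
  a several-fold regional spread of stroke incidence, the dominant
  subtype in the emulated setting).
- **Truth**: per-sex, per-subtype proportional hazards over the four
  predictors with epidemiologically plausible log-hazard ratios (e.g.
  age 0.07/yr, smoking 0.6 for coronary vs 0.35 for stroke, SBP
  0.016–0.022/mmHg); baseline rates 0.004/py (coronary) and 0.008/py
  (stroke) at the centring point for women, ×1.3 for men. Latent subtype
  times are exponential by default (Weibull shape optional) — chosen so
  event probabilities have closed forms that serve as independent test
  oracles.
- **Follow-up**: administrative horizon 12 years; loss to follow-up is an
  independent exponential censoring time calibrated so ≈ 1% of
  participants are lost before the horizon (these are censored, not
  dropped). Observed follow-up is the minimum of the subtype times and
  the censoring time; the subtype label is the argmin of the latent
  times. Each row also carries pre-drawn inclusion uniforms so that
  narrower outcome-definition variants (which count only a stated
  fraction of each subtype's events) are deterministic given the seed.
- **Eligibility injection**: stated fractions of rows get prior
  cardiovascular disease (5%), age under 40 (3%) or missing BMI (0.1%),
  so the filter stage always has work; exclusions are counted by first
  matching reason in the fixed order age → prior disease → missing BMI.
- Ages are uniform on the region's range (40–79 by default); matching a
  real cohort's age distribution is not attempted.

What the generator does *not* emulate: the empirical joint covariate
distribution of any real cohort, competing non-CVD mortality (omitted by
default; the KM "observed risk" is therefore a net risk — the same
convention the validation statistics assume), secular trends, and
measurement error. Passing tests demonstrate the machinery is correct
under the stated proportional-hazards world, not that any particular
published model is well calibrated for a real population.

## Pipeline and reproducibility

`run_study` executes simulate/load → eligibility filters → outcome
mapping (first-event rule; subtype-specific outcomes are not censored by
the other subtype) → scoring → validation (per region × sex and overall,
both sexes always analysed separately) → recalibration → validation →
DerSimonian–Laird pooling. All randomness flows from one top-level seed
through named SHA-256-derived sub-streams; re-running a config
byte-reproduces `metrics.csv`. Reports include the per-stratum metrics
CSV, decile calibration CSV and plots, exclusion accounting, a locked
config with hash, and a markdown summary laid out as a regional
before/after table.

Problem sizes: the test suite runs the replica at 1 000–4 000
participants per region and the brute-force concordance checks at
n ≤ 200; `scripts/acceptance.py` uses 4 000 per region (≈ 37 000
analysed). At these sizes the replica's qualitative findings are stable
across seeds: fourfold underestimation before recalibration, P/O ≈ 1
after in every region, overall C gain ≈ +0.02–0.03 per sex, per-region C
essentially unchanged, combined (meta) pooled C nearly unchanged.

## Known limitations

- The analytic C variance is a first-order projection estimate; for very
  small strata the bootstrap option is preferable.
- The Nam–D'Agostino merge rule operates on group aggregates (weighted
  means; independent-group variance pooling) rather than re-running KM on
  merged members; with zero-event groups the two coincide.
- Exact exponential arithmetic bounds the risk-scale P/O ratio: under a
  pure k-fold baseline-hazard mismatch, `(1−e^{−x})/(1−e^{−kx})` lies
  strictly inside (½, 2) for k ∈ {½, 2}, so only larger mismatches can
  push P/O outside [0.5, 2].
- Competing-risk (Aalen–Johansen) observed risks are not implemented; the
  simulator's no-competing-death default keeps KM unbiased for the
  simulated truth.
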