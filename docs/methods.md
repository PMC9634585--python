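# Methods

This note documents the models implemented in `regburden`, the parameter
conventions, the numerical choices that affect results, and the scope of the
synthetic data generator. All empirical numbers quoted here are either inputs
the user supplies or quantities the package computes from them.

## 1. Data model

Three input tables, delimited text with ISO-8601 dates:

* **population** — `person_id, sex, birth_date, death_date, immigration_date,
  emigration_date` (the last three optional per person).
* **events** — `person_id, condition_code, event_date, source`; one row per
  diagnosis contact.
* **conditions** — one row per severity state; condition-level columns
  (class, category, remission rate, symptomatic fraction, uncertainty bounds)
  repeated across a condition's rows. Conditions are either mental/substance
  use disorders (MSD) or general medical conditions (GMC); GMCs carry one of
  nine broad categories (circulatory, endocrine, pulmonary, gastrointestinal,
  urogenital, musculoskeletal, haematological, cancers, neurological).

Internally all dates are proleptic-Gregorian ordinal day numbers; missing
dates are encoded as −1. Intervals are half-open `[start, end)` in whole days
and converted to years at 365.25 days per year.

## 2. Cohort construction

Follow-up entry is the latest of birth, immigration, and the study start;
exit is the earliest of death, the 95th birthday, emigration, and the study
end. A person contributes the window `[entry, exit)`; windows with
`entry ≥ exit` contribute nothing. When several exits fall on the same day
the recorded reason follows the priority death > age-95 > emigration >
administrative censoring (the person-time is identical either way). The 95th
birthday is computed on the calendar (February 29 births map to February 28
in non-leap years).

A lookback window from `lookback_start` (default 1995-01-01, five years
before the default study start of 2000-01-01) to study entry identifies
prevalent cases: persons whose first diagnosis precedes entry are prevalent
and their episode is in progress at entry; diagnoses before the lookback
start are ignored.

## 3. Episodes

Each diagnosis event opens an episode. The expected duration of an MSD
episode is the reciprocal of its annual remission rate, rounded to the
nearest whole day with a one-day floor; remission rates may be stratified by
sex and age at onset. GMCs have remission rate 0 and are chronic: their
episodes stay open until censoring. A sampled mode (exponential durations
with the same mean) exists for simulation studies; the analysis pipeline uses
expected durations.

Episodes of the same condition merge when the first episode's end is strictly
after the second's onset (episodes that merely touch do not merge), so repeat
diagnoses within an ongoing episode extend it rather than double-count.
Episodes are then clipped to the follow-up window; episodes that remit before
entry are dropped, and an episode truncated by exit is censored.

## 4. Disability weights

* Severity-weighted DW: `w = Σ pᵢwᵢ / Σ pᵢ` over a condition's health states.
  Proportions may sum to less than 1; normalising by Σpᵢ reflects that
  register-ascertained cases are in some symptomatic state.
* Intermittent conditions are scaled by a symptomatic fraction
  (`effective DW = w × f`), equivalent to counting only symptomatic time.
* Concurrent conditions combine multiplicatively:
  `combined = 1 − Π(1 − wᵢ)`, bounded below 1.
* The combined weight is attributed back to the active conditions in
  proportion to their individual weights. This is a reporting convention, not
  a causal claim: the multiplicative interaction term has no unique owner,
  and proportional attribution is the standard symmetric choice. Attribution
  is exactly conservative by construction (see §8).

## 5. Burden engine

Each person's window is segmented at episode onsets and ends; within a
segment the active condition set is constant, so YLDs accrue linearly. This
interval algebra is algebraically identical to a day-by-day accumulation and
is verified against a brute-force daily oracle in the test suite.

* **Population YLDs**: Σ over segments of `years × attributed weight`,
  reported absolutely and per 100,000 person-years, for all conditions or any
  subset (e.g. MSDs only).
* **HeLP** for an index disorder: attributed YLDs accrued by exposed persons
  during `[first index diagnosis (or entry, if prevalent), exit)`, divided by
  those exposed person-years. The pseudo-index `any_msd` uses the earliest
  diagnosis of any MSD. The decomposition reports the index disorder, other
  MSDs individually, and GMCs by category (or individually on request), and
  sums exactly to total HeLP. Age-banded results (default 5-year bands, open
  band from 75, capped at 95) split person-time exactly at band-boundary
  birthdays; band person-years sum to total exposure.

## 6. Privacy grouping

Reported comorbidity cells with fewer than `threshold` (default 5) distinct
contributing individuals are merged, smallest first (ties alphabetical),
within their broad category into `other <category>`; category aggregates
still below threshold merge across categories into `Other`, absorbing the
smallest kept cells if needed. Counts and contributions are summed
additively. Caveat: summing *distinct-person* counts across merged cells
upper-bounds the distinct persons in the merged cell when one person
contributes to several source cells; the merged count is reported as the sum
for exact conservation and auditability.

## 7. Uncertainty

Percentile bootstrap, default 1000 iterations. Each iteration resamples
persons with replacement (resampled copies are relabelled so duplicated
persons remain distinct) and draws one value per uncertain parameter —
disability weights, remission rates, symptomatic fractions — from a
triangular distribution on `[lower, upper]` with mode at the point value,
shared across all persons in the iteration (parameter uncertainty, not
individual noise). The point estimate comes from the unperturbed full data;
the interval is the 2.5th/97.5th percentile of the bootstrap distribution.
The run aborts if more than 1% of iterations fail. Degenerate inputs (no
sampling variability, perturbation off) yield zero-width intervals.

## 8. Numerical choices

* Durations round to whole days (`round(years × 365.25)`, minimum 1 day);
  person-time is exact integer day arithmetic divided by 365.25.
* The proportional attribution closes its floating-point remainder on the
  largest-weight condition, so shares sum to the combined weight exactly
  (to the last bit) and zero-weight conditions receive exactly 0.
* Total HeLP is defined as the sum of its decomposition buckets, making
  conservation exact rather than approximate.
* Episode merging uses strict inequality (`end > next onset`); two episodes
  that share only a boundary day remain separate but contribute identical
  person-time either way.
* Reporting rounds HeLP to two decimals and rates to whole numbers per
  100,000.
* All randomness derives from user-supplied integer seeds via NumPy
  `SeedSequence` spawning; identical configs yield byte-identical outputs.

## 9. Synthetic register generator

The generator exists to exercise the pipeline and support oracle,
conservation, and recovery tests at desk scale; it is *not* a calibrated
model of any real population. It emulates:

* births spread uniformly over a 95-year span before the study end; 50/50
  sex; an immigrant fraction with entry after birth;
* piecewise-constant mortality and disorder-incidence hazards over age bands,
  with an optional male multiplier, sampled by exponential inversion;
* elevated GMC hazards after a first MSD diagnosis via multiplicative rate
  ratios (keyed by GMC code or category), implemented with memoryless
  segment-wise exponential clocks;
* repeat diagnoses while an expected-duration episode is active, at a
  configurable rate;
* diagnoses observable only between max(birth, immigration, lookback start)
  and min(death, emigration, study end).

It does not model: secular trends, seasonality, family clustering,
socioeconomic covariates, treatment effects, diagnostic drift, or
register-specific coding behaviour. Default problem sizes in the test suite
(cohorts of tens to a few hundred persons; 20,000 for recovery tests) are
choices made for runtime, not estimates of any real register's size.

## 10. Limitations

* Disability weights, severity distributions, remission rates, and
  symptomatic fractions are user inputs; results are conditional on them.
* Expected-duration episodes ignore individual duration variability; the
  bootstrap propagates parameter uncertainty, not duration stochasticity.
* Proportional attribution of the comorbidity interaction is one of several
  defensible conventions; alternatives would change the decomposition but
  not total HeLP.
* The 95-year age cap and 365.25-day year are conventions, not estimates.
* Privacy grouping guards against small published cells only; it is not a
  formal disclosure-control guarantee.
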