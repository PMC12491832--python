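# Methods

This note documents the models and procedures implemented in `batphen`,
the assumptions behind the synthetic-data generator, the numerical choices
made where the design was genuinely open, and what the test suite does and
does not demonstrate.

## Calendar and pass reconstruction

Bat years run 1 July–30 June and are labelled by the July year; bat days
run noon to noon and are labelled by the date of the starting noon, with
the noon instant itself opening the new bat day (half-open convention
`[12:00, 12:00)` — "noon to noon" is ambiguous at the boundary, and a fixed
convention is required for testability).  All timestamps are naive local
time; no DST arithmetic is applied because phenology is resolved at daily
scale.

Pass building pairs hits greedily, left-to-right in time, within one tag
and entrance: an inner and an outer hit within `pairing_window_seconds`
(default 60 s; a 20 cm crawl takes seconds) form one directed pass.
Same-reader re-triggers within `burst_window_seconds` (default 5 s) are
first collapsed to the earliest hit.  Greedy chronological pairing is not a
globally optimal matching; at realistic traffic levels (individual crossings
separated by minutes to months) the two coincide, and the greedy rule is
deterministic and order-independent.  Every hit is consumed by exactly one
pass; unpaired and single-reader (`only`) hits yield direction-unknown
passes.

## Longest-gap extraction

Candidate gaps are consecutive pass pairs of one tag within one bat year.
A gap is eligible iff its opening bat day lies in [1 Jul, 1 Feb] and its
closing bat day in [31 Dec, 30 Apr]; both windows are treated as inclusive
on both ends (the laxer reading of "between", applied uniformly).  The
record is the eligible gap of maximal duration; ties break to the earliest
start (an arbitrary but deterministic rule).  Gap endpoints are the bat
days of the bounding passes themselves, not ±1 day: the hibernation bout is
the interval *without* a recorded pass, delimited by recorded passes.
Duration uses true calendar arithmetic (leap years exact).

In dual-reader mode the *selected* gap must open with a confirmed entry and
close with a confirmed exit; otherwise the record is discarded with no
fallback to the next-longest eligible gap.  Candidates are restricted to
passes within the focal bat-year span; gaps bounded by the previous
spring's passes are not considered.

Power outages and similar known artefacts are handled by masking rules
(species or `both` × bat year × variable); masking a start or end also
masks the duration, never touches other fields, and is idempotent.  No
outlier filtering is applied beyond the calendar windows, so records
distorted by mid-winter arousals or missed entry passes remain in the
dataset by design.

## Validation procedures

*Single-reader reanalysis* keeps one reader position per entrance
(configurable, default inner), rewrites it to `only` and re-extracts in
single mode; end-date concordance is the fraction of (tag, bat year) keys
present in both tables with exactly equal end dates.  *Final departure* is
the first direction-confirmed exit after the end-date bat day's opening
noon that is not followed by an entry within 24 h; the 24-h lookahead uses
exact timestamps (an interval statement), while the "<1 week" criterion is
a strict `< 7` on bat-day differences (the literal reading of "less than
one week").  Whether a calendar-day or 168-hour rule was intended is not
derivable from the definition; the bat-day difference is used because end
dates themselves are daily quantities.

## Mixed models and marginal slopes

Responses are encoded as integer day indices from 1 July of the bat year
(starts ≈ 60–215, ends ≈ 183–304) and duration in days, keeping signs
interpretable across both species.  Per species:

* **Year trends** — `y ~ year_c * class + (1 | individual)` with the year
  covariate centred at the first bat year (numerical stability only; slopes
  unaffected).  Fitted separately for start, end and duration.
* **Temperature effects** — `y ~ temp * class + (1 | bat year)` where
  `temp` is the median of all hourly temperatures in a species- and
  response-specific 2-month window: Aug–Sep (start) and Feb–Mar (end) for
  *M. daubentonii*, Nov–Dec and Jan–Feb for *M. nattereri*.  Window months
  ≥ July resolve to the bat year's own calendar year, months < July to the
  following one.  Only the bat-year random intercept is used — no
  individual effect — matching the model family this mirrors.

Estimation is REML via statsmodels `MixedLM`; p-values are Wald/normal.
The per-class marginal slope is the covariate coefficient plus the
class-specific interaction contrast, with standard errors from the fixed-
effect covariance; this is invariant to the contrast coding and class
ordering (tested).  The *overall* slope is the unweighted mean of the four
class slopes — an estimated-marginal-means-style average, chosen because it
exactly reproduces the arithmetic relation between published per-class and
overall phenology trends of this design; sample-size weighting would tie
the overall estimate to the cohort structure.  A degenerate mixed fit
(zero variance component, non-convergence, NaN standard errors) drops to an
OLS fixed-effects fit and is flagged on the results object; with noise-free
data this path reproduces the exact linear structure.

The temperature model refuses to fit with fewer than 3 distinct window
temperatures; collinearity of the median with the min/max of daily means
can be checked with `temperature_collinearity`, which flags constant
summaries instead of reporting undefined correlations.

## Synthetic-data generator

The generator emulates the study conditions this pipeline targets: 13 bat
years (2010–2022), up to 150 newly tagged individuals per species per year
(half juvenile at tagging), annual survival 0.7 (yielding ~2.5 records per
individual, an unbalanced panel like real mark–recapture data), and a
four-class phenology model

    entry day  = class baseline + trend·(year − year₀)
               + temp_effect·(window median − long-run window mean)
               + individual intercept + residual,

with individual intercepts Normal(0, 8 d) shared between entry and exit,
residuals Normal(0, 6 d) drawn independently per event, and exit analogous
(temperature coupling off by default).  Class baselines put *M.
daubentonii* underground roughly October–mid-April and *M. nattereri*
December–mid-March, with adult females entering earliest and emerging
latest.  Default trends and entry temperature sensitivities follow the
magnitude and sign structure reported for this system (entry advancing up
to ~2 days/year in one species, delaying in the other; entry sensitivity up
to ~9 days/°C).  Within-class variance magnitudes are this package's
assumptions — no published distributional detail exists — and are stated
here, not claimed as field estimates.

Weather is hourly: annual mean 10 °C, seasonal amplitude 8 °C (coldest
mid-January), warming 0.04 °C/year, hourly noise SD 3 °C, plus a
per-bat-year anomaly (SD 0.8 °C).  The anomaly term is essential: without
interannual variation in the 2-month window medians the configured days/°C
effect would be unidentifiable.  Temperature coupling uses the deviation of
the window median from its long-run mean so the configured coefficient is
directly the estimand of the temperature model.

Events: each true entry/exit becomes an ordered reader-hit pair separated
by `crossing_seconds` (5 s) at a uniform instant in the night (18:00–06:00,
bats being nocturnal); swarming visits (Poisson, mean 2 per individual-year)
fall uniformly in the 30 nights before entry and contribute an entry/exit
pair within the same night; a mid-winter arousal (probability 0.05)
contributes an exit and next-night re-entry; each hit is dropped
independently with probability 1 − `p_detect` (default 0.98) and outage
windows delete hits wholesale.  Draws violating the calendar constraints
(entry by 1 Feb, exit in [31 Dec, 30 Apr], entry < exit) are redrawn up to
10 times then clamped with a logged warning.  Dates are rounded half-up to
whole days; the truth table also keeps the pre-rounding fractional day
values, which is what noise-free exactness tests regress on (rounding to
dates quantizes slopes at the ~0.01–0.03 days/year level).

What the generator does *not* emulate: movement between hibernacula,
within-winter torpor bout structure, tag loss or failure, clock drift
between loggers (single-reader behaviour is represented by the `only`
reader state instead), weather realism beyond sinusoid + trend + anomaly +
noise, and body-mass dynamics.  Passing tests therefore demonstrate the
correctness of the pipeline's logic and the recoverability of effects under
the stated model — not robustness to every field pathology.

## Problem sizes and test design

Oracle equivalence of the gap extractor is checked against brute-force
enumeration on 1000 random pass streams in both modes.  Parameter-recovery
checks run the *full* pipeline (render → passes → extract → fit), not
truth shortcuts: year trends at 13 years × 150 tags/species/year over 20
seeds (mean per-class error ≲ 0.03 days/year, tolerance ±0.3; null runs
centred within 0.1), temperature effects at the same scale over 10 seeds
(tolerance ±1.5 days/°C).  Recovery is demonstrated on the entry response;
end and duration responses use the same machinery and are covered by the
noise-free exactness tests.  Year-trend recovery runs with temperature
coupling off, and temperature recovery with year trends and warming off, so
the configured coefficient is exactly the estimand of the model being
checked.  Degradation runs use 5 bat years × 30 tags/species/year over 20
seeds across `p_detect` ∈ {1.0, 0.95, 0.9, 0.8}; dual-mode record counts
fall steeply with missed hits, while end-date concordance decays only
slightly (~10⁻⁴ per step) because most detection failures remove a record
from one analysis rather than changing its end date — disagreements
require a mid-winter arousal with an asymmetric hit loss.

## Known limitations

* Greedy pairing can mis-pair hits when two crossings of the same tag at
  one entrance interleave within the pairing window; such traffic is not
  generated and was not observed to matter at realistic rates.
* The "overall" slope definition (unweighted class mean) is an assumption;
  a sample-size-weighted average would differ where cohorts are unbalanced.
* Wald/normal p-values ignore finite-sample degrees-of-freedom corrections
  (Satterthwaite/Kenward–Roger); with thousands of records the difference
  is negligible, but small datasets should be interpreted accordingly.
* The single-reader era is represented only through the `only` reader
  state; desynchronised-clock artefacts of real paired loggers are not
  modelled.
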