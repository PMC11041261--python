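# Methods

This note documents the models, rules and numerical choices implemented
in `vox2mets`, and what the synthetic cohorts do and do not demonstrate.

## Diary model

An utterance is one transcript string with an input timestamp. The
grammar is anchored on five trigger words — *start, end, from, to, do* —
over text normalized to lower case with punctuation stripped to spaces
(`:` and `'` are kept so clock tokens survive). Clock times are 24-hour
`H:MM` / `HH:MM` / `H o'clock`; there is no AM/PM inference — an
ambiguous time is left to manual review rather than guessed. Recognized
patterns produce one *auto* record; `start <activity> now` opens a
session stamped with the utterance's input time and is closed by a later
`end <activity> now`. Parsing is **total**: any other text yields a
single *failed* record, never an exception, mirroring a workflow where
non-convertible entries are checked and converted by hand
(`manual_override`). When the start- and end-clauses of one utterance
name different activities, the first wins and the mismatch is logged.
*do* introduces an activity word but creates no record alone.

Records never cross midnight (`0 ≤ start < end ≤ 1440`); an overnight
activity must be split at 00:00 upstream, which keeps per-day accounting
exact. Overlapping records on one day are resolved **last entry wins**
by utterance input time: a deterministic rule that matches the
"corrected later" usage pattern; truncations and drops are logged.

## MET assignment

The behavior→MET table is a packaged, editable CSV
(`label,synonyms,met_value,category`, synonyms `|`-separated) — a
~50-row subset of the 2011 Compendium of Physical Activities. Matching
is exact-token over labels and synonyms (tokens are unique table-wide);
there is no fuzzy matching, and an unmatched word is returned as
*not-found*, never silently defaulted. Two values are pinned by design:
`training` = 5.0 METs, and `sleep` = 0.9 METs — the same constant used
to impute accelerometer non-wear, keeping the two instruments'
arithmetic mutually consistent. All intensities lie in [0.9, 20.0].

## Daily summaries

Minute intervals are half-open `[start, end)` so adjacent records never
double-count a minute. Daily MET·minutes is the per-minute sum of
intensity over covered minutes; the average daily MET divides by the
covered-minute count. **No imputation is applied on the diary side**:
uncovered minutes simply do not enter the average. The 0.9-MET
imputation belongs exclusively to the accelerometer's 24-hour average.
This asymmetry is deliberate — it is what makes whole-day diary means
systematically exceed accelerometer 24-h means while time-matched means
coincide, and it is exercised by the tests.

## Accelerometer model

Input is device-exported METs at 10-s epochs, 8640 per day, in a
delimited file (`participant,date,epoch_index,met`); missing epochs are
zero-filled with a warning, duplicates and negative values are errors.
An epoch is a *zero count* when its value is at or below
`zero_threshold` (default 0.0 METs; the device's true detection
threshold is unpublished, so this is a configuration knob, not a claim).
A maximal run of zero counts **strictly longer than 60 minutes**
(> 360 epochs) is non-wear — a run of exactly 60 minutes counts as wear;
the boundary is unit-tested. Runs are found on epochs and projected to
minutes (a minute is non-wear only if all 6 of its epochs lie inside a
qualifying run), preserving the 10-s resolution of the rule while
producing the minute mask the analyses need. Wear time is 24 h minus
non-wear; the valid-day rule keeps days with wear ≥ 10 h (inclusive).
Sleep receives no special handling: participants removing the device
overnight appear as non-wear and receive the 0.9 imputation, exactly as
the arithmetic implies.

## Validation analyses

The unit of analysis is the participant-day; no within-participant
clustering correction is applied. The accelerometer ≥ 10 h wear filter
applies in **all** modes; the diary-hour thresholds (10 h / 14 h) define
mode membership; the matched mode keeps days whose diary-covered ∧ worn
minute set is non-empty. Statistics:

* paired t-test (two-sided) on voice − accelerometer daily means; a
  zero-variance difference vector is reported as an explicit degenerate
  flag, never as p = 0;
* Pearson r with its two-sided p; constant series are flagged;
* Bland–Altman: mean difference, SD with the n−1 denominator, limits of
  agreement at mean ± 1.96·SD, and a trend test — OLS of difference on
  pairwise mean with slope, intercept, r and two-sided slope p. The
  difference direction is fixed by contract as **voice − accelerometer**
  (reported directions in this literature are not always explicit, so
  the contract is documented rather than inferred).

t-test, correlation and regression are computed with `scipy.stats`
(`ttest_rel`, `pearsonr`, `linregress`); the test suite checks them to
12 significant digits against frozen closed-form computations done in
plain numpy.

## Synthetic cohorts

The generator is a forward model of the study conditions, not a
behavioral simulation. A **template day** — overnight sleep, grooming,
meals, commute walking, two study blocks, an optional sport (p = 0.5
per day, drawn from training/running/basketball/tennis/swimming),
bathing, evening TV, bedtime sleep — is jittered per participant-day
(boundary jitter up to ±25 min by slot), leaving 5–70 min unreported
gaps between activities as real diaries do. The default cohort is
20 participants × 7 days (140 participant-days, the canonical design).
All labels resolve in the compendium, whose MET value is the ground
truth.

Noise knobs (`NoiseSpec`): `p_record_missing` (an interval is never
spoken), `p_trigger_omission` (an utterance is emitted in a
non-parseable form drawn from the known failure phrases and templated
variants), `accel_sigma` (per-epoch Gaussian intensity noise, truncated
at 0 — the device's true error model is unknown, so this is a knob, not
a claim), `met_bias` (additive offset on the device signal during sports
intervals, modeling intense exercise exceeding the diary's fixed
compendium value), `nonwear_blocks` and `sleep_nonwear` (device removed
overnight). Defaults are all zero/off.

What passing tests show: the pipeline's bookkeeping is exact (zero-noise
cohorts round-trip bit-for-bit and the matched-mode mean difference is
exactly 0), the agreement statistics are correct, and the qualitative
signature of whole-day overestimation vs time-matched agreement follows
from the imputation/coverage asymmetry. What they do not show: anything
about real speech-recognition error, real behavioral time-use
distributions, or real device error — the template day and the noise
model are interpretable stand-ins, not empirical claims.

## Numerical choices

* Minute means of 6 epochs, and the 24-h average with imputation, are
  accumulated in extended precision (`np.longdouble`) and cast back to
  float64, so a minute of six identical epochs reproduces that value
  bit-for-bit and a fully imputed day averages to exactly 0.9. This is
  what makes the zero-noise end-to-end identity exact rather than
  approximate.
* Exact duplicate records collapse to one; fully shadowed records are
  dropped with a log entry.
* Degenerate statistics (zero-variance differences, constant series,
  constant pairwise means) return explicit flags with NaN values.
* Cohort generation and all noise draw from `numpy.random.default_rng`
  seeded explicitly; identical spec + seed gives identical output.

## Pipeline and configuration

All study constants — 10 h wear threshold, 10 h/14 h diary thresholds,
0.9 MET imputation, 1.96 LoA multiplier, 0.0 zero-count threshold —
live in `RunConfig` with those values as defaults, so sensitivity
analyses need no code change. Transcripts carry an optional
`participant` column, required for end-to-end pairing (the parser itself
does not need it). The run manifest omits wall-clock timestamps so
re-running with identical inputs produces hash-identical artifacts; it
records parse-mode counts satisfying auto + manual + failed = total.

## Known limitations

* The grammar is English-token based; morphological analysis of other
  languages, and free-text activity inference beyond the trigger
  patterns, are out of scope.
* AM/PM ambiguity and overlapping retrospective corrections are resolved
  only by the deterministic last-entry-wins rule plus manual review.
* The compendium subset is a practical default, not a reconstruction of
  any specific study's table; users should substitute their own CSV for
  real analyses.
* Agreement statistics treat participant-days as independent; repeated
  measures within participant are not modeled.
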