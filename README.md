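# vox2mets

Evaluation pipeline for **voice-diary physical-activity assessment**:
it turns speech-recognized diary transcripts into minute-level MET
(metabolic equivalent) timelines and validates them against triaxial
accelerometer epoch data using paired t-tests, Pearson correlation and
Bland–Altman agreement.

## Who this is for

Researchers in physical-activity epidemiology who collect self-reported
behavior by voice ("study from 9:00 to 12:00") and need a reproducible,
auditable way to (a) convert such utterances into daily energy-expenditure
summaries and (b) quantify agreement with a reference accelerometer.
Because raw participant data from such studies are rarely shareable, the
package ships a synthetic-cohort simulator that generates paired
transcript + epoch streams from a known true activity schedule, so the
entire pipeline — and its statistics — can be tested end to end.

## The method

**Diary side.** Utterances are segmented with five trigger words
(*start, end, from, to, do*). Recognized patterns (`<activity> from t1
to t2`, `start <activity> at t1 … end <activity> at t2`,
`<activity> start t1 end t2`, and `start <activity> now` sessions)
auto-convert to timed records; everything else becomes a *failed* record
routed to a manual-review queue. Each activity word maps to an intensity
via a behavior→MET compendium table (a packaged ~50-row subset of the
2011 Compendium of Physical Activities; *training* = 5.0 METs, *sleep* =
0.9 METs). Records paint a 1440-minute daily grid; daily MET·minutes are
Σ intensityᵢ·1 min over covered minutes, and the **average daily MET**
is that total divided by the covered time.

**Accelerometer side.** Device-exported METs at 10-s epochs (8640/day).
A maximal run of zero-count epochs strictly longer than 60 min is
**non-wear**; wear time = 24 h − non-wear; days with ≥ 10 h wear are
valid. The 24-h average substitutes 0.9 METs for every non-wear minute.

**Agreement.** Three analysis modes — days with ≥ 10 h or ≥ 14 h of
diary coverage, and a **time-matched** mode restricting both instruments
to the minutes where diary coverage and device wear coexist. Per mode:
paired t-test, Pearson r, and Bland–Altman statistics
(d̄ ± 1.96·SD limits of agreement, with an OLS trend test of difference
on pairwise mean; difference is defined as voice − accelerometer).

## Worked example

Simulate the canonical 20-participant × 7-day cohort with realistic
compliance noise (10% of intervals never spoken, 10% of utterances in a
non-parseable form, 0.15-MET epoch noise, device removed during sleep),
run the full pipeline in memory, and print the per-mode agreement:

```python
import numpy as np
from vox2mets import (CohortSpec, NoiseSpec, generate_schedule,
                      default_compendium, cohort_days, report)

table = default_compendium()
schedules = generate_schedule(CohortSpec(), seed=42, table=table)  # 140 days
noise = NoiseSpec(p_record_missing=0.1, p_trigger_omission=0.1,
                  accel_sigma=0.15, sleep_nonwear=True)
days = cohort_days(schedules, noise, table, rng=np.random.default_rng(42))
for mode, rep in report(days).items():
    ba = rep.bland_altman
    print(f"{mode:8s} n={rep.n_days:3d}  voice {rep.voice_mean:.2f} ({rep.voice_sd:.2f})"
          f"  accel {rep.accel_mean:.2f} ({rep.accel_sd:.2f})"
          f"  diff {ba.mean_diff:+.3f}  LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]"
          f"  r={rep.correlation.r:.3f}")
```

Output:

```
ge10h    n=130  voice 1.48 (0.22)  accel 1.35 (0.13)  diff +0.134  LoA [-0.170, +0.438]  r=0.709
ge14h    n=114  voice 1.44 (0.17)  accel 1.34 (0.12)  diff +0.098  LoA [-0.096, +0.292]  r=0.803
matched  n=140  voice 1.97 (0.29)  accel 1.97 (0.29)  diff +0.000  LoA [-0.005, +0.005]  r=1.000
```

Reading this: in the whole-day analyses the diary mean *exceeds* the
accelerometer 24-h mean — the device spends unreported gaps at measured
zero and long idle blocks at the 0.9-MET imputation, while the diary
averages only over reported (mostly active) time. In the time-matched
analysis the two instruments see the same minutes, so the means
coincide and the correlation is near perfect; only unbiased epoch noise
separates them. The matched means sit higher than either whole-day mean
because sleep (non-wear) is excluded from the matched minute set.

## Command line

```bash
vox2mets simulate --participants 20 --days 7 --seed 42 --out sim/
vox2mets run --transcripts sim/transcripts.csv --epochs sim/epochs.csv --out results/
vox2mets validate --transcripts T.csv --epochs E.csv --compendium C.csv --mode all --out results/
```

`run` writes parsed records, per-day timelines, accelerometer summaries,
per-mode pair tables and plot point sets (`scatter_<mode>.csv`,
`bland_altman_<mode>.csv`), `report.json`, a manual-review queue, and a
run manifest with parse-mode counts. Exit codes: 0 ok, 1 input error,
2 empty analysis set.

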