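# emgfatigue

Fatigue apportionment for isokinetic cycling trials. The package turns raw
cycling-trial signals — multi-muscle surface EMG, crank torque/angular-velocity
records, breath-by-breath gas exchange and inspiratory-capacity manoeuvres —
into:

* a baseline relationship between composite fractional EMG and single-leg
  isokinetic power (least-squares, per visit),
* a decomposition of the end-exercise drop in maximal isokinetic power
  (performance fatigue, PF) into **activation fatigue** (AF, the power
  equivalent of the drop in maximal evocable EMG) and **muscle fatigue**
  (MF = max(0, PF − AF)),
* dynamic-hyperinflation lung-volume endpoints (IC, 20 s tidal volume,
  IRV = IC − VT) at baseline, isotime and the limit of tolerance,
* paired-comparison and correlation tables across control, expiratory-resistance
  and isotime-control conditions.

A fully deterministic synthetic-trial generator (`emgfatigue.synth`) emulates
the whole protocol with known ground truth, so every stage is testable without
any data download.

## Layout

| module | role |
| --- | --- |
| `emgfatigue.synth` | synthetic baseline sessions and constant-power trials with a truth sidecar |
| `emgfatigue.sigproc` | Butterworth band-pass, trailing RMS envelope, revolution segmentation, 3-revolution isokinetic power paired with composite fractional EMG |
| `emgfatigue.fatigue` | baseline regression, PF/AF/MF decomposition, intolerance detection, power reserve |
| `emgfatigue.lungmech` | IC manoeuvre reconciliation, 20 s tidal volume, IRV, hyperinflation deltas |
| `emgfatigue.stats` | dependent t-tests with 95% CI of the difference, Pearson correlations, the study report |
| `emgfatigue.io` / `pipeline` / `cli` | delimited-table formats, orchestration, command-line interface |

## CLI

```sh
# simulate a 14-participant cohort, analyse everything, write all reports
emgfatigue all --n 14 --seed 1 --out cohort_out

# or stage by stage
emgfatigue simulate --n 3 --seed 1 --out cohort_out
emgfatigue process   --trial-dir cohort_out/data/p001/resistance --out features.csv
emgfatigue baseline  --features features.csv --out baseline.json
emgfatigue decompose --features features.csv --baseline-json baseline.json \
                     --task-power 193 --out fatigue.csv
emgfatigue lung      --trial-dir cohort_out/data/p001/resistance --out lung.csv
emgfatigue stats     --summaries cohort_out/results/summaries.csv --out stats_out
```

Exit codes: `0` success, `2` validation error, `3` computation error. A YAML
config can be passed with `--config`; explicit flags override it. All defaults
and library versions are echoed once into `results/run_log.txt`.

## Data formats

Plain delimited text (comma or tab, auto-detected), header row required:

* EMG: `time_s, vl_mv, rf_mv, vm_mv, lg_mv` (2000 Hz)
* crank: `time_s, angle_deg, torque_left_nm, torque_right_nm, omega_rad_s, mode`
  (2° angular sampling; `mode` is `hyperbolic` or `isokinetic`)
* breaths: `time_s, vt_l, ve_l_min, vo2_l_min, vco2_l_min`
* IC manoeuvres: `time_s, stage, replicate, inspired_volume_l`
* truth sidecar: `time_s, true_max_emg_fraction, true_muscle_deficit_w, true_irv_l`

## Conventions worth knowing

* PF/AF/MF are single-leg watts; the power reserve is chainring
  (twice one-leg) watts.
* Zero-phase (forward-backward) filtering; trailing 200-sample RMS window.
* Isokinetic revolutions are accepted within ±5% of the target cadence; among
  qualifying 3-revolution runs the one with the highest mean left-crank power
  wins, ties going to the earliest.
* Visit maxima for EMG normalization are taken over **all** isokinetic bouts of
  a visit (baseline efforts plus the end-exercise bout); a warning is logged
  when the end-exercise bout sets the maximum.
* AF may be negative (reported, never clamped); only MF is clamped at 0 W.
* Duplicate IC manoeuvres are averaged; replicates differing by more than 10%
  are flagged. Negative IRV is flagged, never clamped.
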