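# gastrogaze

Analysis toolkit for two physiological readouts of disgust in a
child-friendly experimental design, plus a fully synthetic verification
cohort:

* **Electrogastrogram (EGG) band power** — a reusable implementation of the
  gastric data-reduction chain: per-sensor demeaning, Hampel despiking
  (window of one ~20 s normogastric cycle, threshold 3 scaled MADs),
  zero-phase Butterworth band-pass (0.5–10 cycles/min), ICA decomposition
  into four components, component screening by normogastric
  signal-to-noise ratio (peak power in 2–4 cpm over mean power at the
  remaining analysed frequencies, keep ≥ 3), inverse-transform
  reconstruction, Hann/FFT block spectra averaged over sensors, per-band
  summaries (bradygastric 0.5–2, normogastric 2–4, tachygastric 4–10 cpm),
  and the scalar gastric-disgust index
  `ln(normogastric peak power, disgust / neutral)`.
* **Preferential-looking dwell times** — velocity-threshold fixation
  detection, AOI assignment by horizontal span, per-trial dwell and
  missing-data accounting, strict >50% missing-trial exclusion with a
  logged audit trail, the per-participant avoidance score
  (dwell disgust − dwell neutral), and the binned within-trial time course
  of the dwell-share difference.
* **Questionnaire scoring** — declarative instrument specs (item counts,
  response ranges, subscale maps, reverse keying) for the four bundled
  disgust-sensitivity instruments, with flag-and-propagate missing
  handling.
* **Statistics** — explicit candidate sets of linear mixed-effects models
  (random intercepts for participant and parent/carer, ML estimation) with
  a ΔAIC/ΔBIC ledger, and pairwise-complete Pearson correlation matrices.
* **Synthetic data** — seeded generators for gastric recordings (sinusoid
  sources mixed over four sensors, with noise, drift, spikes, and a
  condition-dependent normogastric attenuation `1 − δ`), gaze streams
  (approach-then-avoid fixation structure with blink gaps), and family
  cohorts with latent-factor-correlated questionnaire responses.  Every
  generator returns its ground truth so each downstream stage has a
  recoverable target.

## Test

```bash
python -m pytest -q
```

The suite includes `tests/test_acceptance.py`, which checks the task and
unit arithmetic, the exclusion bookkeeping, the filter/ICA/spectrum
oracles, end-to-end recovery of `ln((1−δ)²)` from synthetic cohorts, the
time-course sign structure, and type-I calibration of the condition effect
over 200 null simulations.

## Command line

```bash
# synthetic data
gastrogaze simulate egg    --config egg.yaml    --out sim/ --seed 1
gastrogaze simulate gaze   --config gaze.yaml   --out sim/ --seed 1
gastrogaze simulate cohort --config cohort.yaml --out sim/ --seed 1

# analyses
gastrogaze egg run  --recording sim/egg.csv --out out/
gastrogaze gaze run --trials sim/gaze_samples.csv --fixations sim/gaze_fixations.csv \
                    --aoi sim/aoi.json --out out/
gastrogaze score    --instrument tdds --responses sim/responses_tdds.csv --out scores.csv
gastrogaze stats ledger    --data dwell.csv --models models.yaml --out out/
gastrogaze stats correlate --data cohort.csv --measures age_months,dsr_total --out out/
```

All on-disk artefacts are plain delimited text, JSON, or YAML; formats are
documented in `gastrogaze/io.py`.

## Conventions worth knowing

* Gastric frequencies are handled in cycles/min throughout (3 cpm = 0.05 Hz).
* AOI span membership is half-open (`x_min ≤ x < x_max`) on the horizontal
  axis only; vertical position is ignored by design.
* Dwell is fixation-duration based by default; a sample-count mode exists
  for sensitivity analyses (`dwell(..., mode="sample")`).
* A component with SNR exactly 3 is kept ("under 3" is excluded).
* A trial with exactly 50% missing samples is retained ("over 50%" is
  excluded).
* Band proportion denominators cover 0.5–10 cpm; a bin at exactly 2 or
  4 cpm counts as normogastric.
* Mixed models use ML (not REML) so AIC/BIC are comparable across
  fixed-effect structures; the bradygastric lower edge (0.5 vs 0.1 cpm)
  and the standardisation SD convention are configurable.
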