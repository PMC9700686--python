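# vrgaze

Head-compensated eye-movement analytics for virtual-reality gaze
recordings, built for two-group (case/control) study designs in which
children or adults perform naturalistic tasks in a head-mounted display
with a built-in eye tracker sampling at ~90 Hz.

The package covers the full analysis chain of such a study:

* **Synthetic sessions** — a generator that produces ground-truth-annotated
  gaze streams for a two-group cohort (default 37 ADHD / 36 control
  participants, 13 scenarios of 90 s each), calibrated so that the
  post-filter means of fixation duration, saccade duration and saccade
  amplitude reproduce published group statistics exactly
  (317/309 ms, 57/67 ms, 5.44/6.29°).
* **Event detection** — gaze is mapped from the head frame to world
  coordinates with the concurrent head quaternion (`world = q ⊗ gaze ⊗ q⁻¹`),
  angular velocity is estimated with the Engbert–Kliegl moving-window
  differentiator, and a sample is saccadic when
  `(v_az/η_az)² + (v_el/η_el)² > 1` with `η_c = λ·σ_c`,
  `σ_c = sqrt(median(v_c²) − median(v_c)²)` and λ = 6 by default.
  Detected events pass the standard plausibility filters
  (saccades 22–300 ms, ≥ 0.75°, ≤ 36 000°/s²; fixations 100–1000 ms).
* **Features** — per-participant × scenario means, fixation-to-object
  (AOI) attribution with relevant/irrelevant/non-object labels,
  Normalized Scanpath Saliency (mean z-scored map value at fixation
  centroids), 1-s ambient/focal time bins, and head-rotation metrics.
* **Group statistics** — Mann–Whitney rank tests reported as |Z|,
  linear-mixed-model likelihood-ratio contrasts
  (`feature ~ group + scenario + (1|participant)[+ (1|order)]`,
  χ² with φ = √(χ²/N)), and Benjamini–Hochberg FDR adjustment per family.
* **Classification** — nested cross-validated PCA+SVM group classifiers
  (scaling and PCA fit on training folds only, grid-searched kernel /
  C / γ / component count, stratified tenfold outer loop, mean ROC AUC),
  plus a 30-iteration bootstrap-CV t-test (df = 58) for comparing two
  feature sets.

## Worked example

Run the whole chain — simulate → screen → detect → features → stats →
classify — on a small demo cohort, from Python:

```python
from vrgaze.gaze_io import load_config
from vrgaze.pipeline import run_pipeline

config = load_config(overrides={
    "cohort": {"n_adhd": 8, "n_control": 8, "n_scenarios": 3,
               "scenario_duration_s": 45.0, "instruction_duration_s": 5.0,
               "seed": 11},
    "classification": {"outer_folds": 8, "inner_folds": 4},
})
manifest = run_pipeline(config, outdir="demo_run")
```

or from the shell: `vrgaze all --outdir demo_run` (add `--config my.yaml`
to override defaults). The run writes `gaze.tsv`, `events_truth.tsv`,
`events.tsv`, `features.tsv`, `stats.tsv`, `auc_report.json` and a
`manifest.json` with per-stage counts. For the config above the manifest
records:

```
simulate: 16 participants, 214151 samples, 12426 ground-truth events
detect:   10533 filtered events
          (removed: 35 by amplitude, 38 by fixation duration, 0 others)
```

and `stats.tsv` contains one row per contrast, e.g. the saccade-duration
group contrast

```
eye_features  mean_sacc_dur_ms:group  chi2  6.148  df 1  p_raw 0.0132  phi 0.620  p_fdr 0.0395
```

meaning: at this small demo size, the 10 ms group difference in saccade
duration built into the generator is already detectable by the mixed
model (χ²(1) = 6.15, FDR-adjusted p = 0.039), while the weaker fixation
and amplitude effects are not. At the full default cohort size the
saccade-duration and amplitude contrasts become highly significant and
the eye-feature classifier reaches a mean AUC around 0.8, clearly above
the performance-measure classifier.

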