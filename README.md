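# voiceaudit

Bias-aware machine-learning audit pipeline for audio-based voice-disorder
screening, built around unilateral vocal fold paralysis (UVFP) as the model
disorder.

Classifiers trained on clinical voice recordings can score well for the
wrong reasons: if controls were cropped to fixed durations while patient
recordings vary, or if the microphone gain was raised for weak voices,
models learn the recording pipeline instead of the pathology. `voiceaudit`
implements the full audit that exposes and mitigates such biases:

1. **Synthetic cohort generation** — matched patient/control voice cohorts
   (source-filter synthesis with controllable jitter, shimmer,
   harmonics-to-noise ratio, f0, pauses, formant damping) with injectable
   *duration* and *gain* recording biases and simulated clinician raters,
   so every downstream claim can be tested against known ground truth.
2. **Acoustic features** — the 88 eGeMAPS-named functionals (in-repo
   extractor on numpy/scipy), a four-statistic cepstral peak prominence
   (CPP) set, and audio duration, each feature tagged by category
   (vocal folds / intensity / vocal tract / spectral balance / prosody).
3. **Redundancy removal** — distance correlation (dcor) and the greedy
   *Independence Factor* deduplication with a threshold sweep and
   parsimonious subset selection.
4. **Evaluation** — four classifiers (L1 logistic regression, elastic-net
   SGD, random forest, MLP) on 50 bootstrapped participant-level
   group-shuffle splits (20% held out, group-balanced), with permutation
   nulls, empirical p-values p = (1 + #{null ≥ median}) / (1 + n), and
   Benjamini–Hochberg correction.
5. **Explainability** — native Kernel SHAP with exact local accuracy,
   performance-weighted mean |SHAP| per model and cross-model weighted mean
   ranks; top-5 / all-minus-top-5 / single-feature experiments.
6. **Bias audit & mitigation** — duration-only probes, intensity direction
   checks, inter-rater reliability (ICC from ANOVA mean squares, Light's
   kappa), clinician screening accuracy, and the mitigation experiment:
   trim readings to the fixed control duration and drop every
   intensity-category feature plus anything dcor-associated with one
   (cutoffs 0.3 / 0.4), then re-evaluate.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import voiceaudit as va

# a biased cohort: pathology + duration/gain recording biases
spec = va.CohortSpec.default_biased(n_per_group=20, seed=42)
cohort = va.generate_cohort(spec)

feats = va.extract_feature_frame(cohort.recordings, "egemaps88")
table = va.build_feature_table(cohort.recordings, cohort.manifest,
                               "egemaps88", "reading", features=feats)
plan = va.make_split_plan(va.participants_frame(cohort), n_splits=20, seed=42)

res = va.evaluate_table(table, plan, ("logreg_l1", "random_forest"))
for m, s in res.scores.items():
    lo, hi = s.ci90
    print(f"{m}: median AUC {s.median:.2f} ({lo:.2f}-{hi:.2f}; "
          f"null {s.null_median:.2f}) p={res.pvalues[m]:.3f}")

probe = va.duration_probe(cohort.recordings, cohort.manifest, plan,
                          model_names=("random_forest",))
print(f"duration-only RF: {probe.scores['random_forest'].median:.2f}")
flags = va.intensity_direction_check(table, va.load_category_map())
print(f"{int(flags['patient_higher'].sum())} intensity features "
      "have a higher patient mean")
```

prints

```
logreg_l1: median AUC 0.75 (0.44-0.95; null 0.54) p=0.190
random_forest: median AUC 0.77 (0.38-0.87; null 0.51) p=0.238
duration-only RF: 0.75
11 intensity features have a higher patient mean
```

Reading: the 88-feature models separate the groups well above their
permutation nulls (at this demo size of 20 participants per group the
empirical p over 20 splits is still coarse; at study scale the models are
significant after correction). The audit lines show why caution is needed —
*duration alone* classifies almost as well as the full feature set, and
eleven intensity features are higher in patients even though a paralyzed
voice is weaker: both are recording artifacts, not biology. Running
`va.mitigation_eval` trims the durations, drops the intensity-associated
features, and reports how much genuine signal survives.

The same stages are available as a CLI
(`voiceaudit synth|features|reduce|evaluate|explain|audit|mitigate|run-all`),
e.g. `voiceaudit run-all --out runs/demo --seed 1`.

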