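# contextmem

Analysis pipeline for **context-dependent memory** experiments in which
learners study vocabulary from two phonetically similar languages inside
distinctive virtual environments, and later recall is probed after cued
*mental reinstatement* of one environment. The package covers the full
analysis chain of such a study — behavioural scoring, multivariate decoding of
the imagined context from 4D brain volumes, template-based reinstatement
fidelity, and the factorial statistics linking fidelity, cue congruency, and
presence to recall — together with a synthetic-data generator that plants the
structure the analysis is meant to find, so every stage can be validated by
parameter recovery.

It is aimed at cognitive-neuroscience researchers who want a reproducible,
testable implementation of this design's analysis (or a simulation sandbox for
planning similar studies) without the original human data, which are not
publicly deposited.

## The measures and models

**Recall scoring.** A verbal response to a cue is scored as the fraction of
correct phonemes, `score = n_correct / n_total`; two independent scorers are
reconciled by averaging. For each word with a non-zero score at the earlier
test, the item-wise **forgetting index** over a delay is

```
f_i = score_late(i) - score_early(i)        f_i ∈ [-1, 1]
```

and the participant's **retention score** is `R = 1 + mean_i(f_i)`: 1 is
perfect retention, 0.5 means half the previously recalled information
survived. Intrusions from the other language are ordinal severity codes 0–3
per scorer; the maximum code wins and the participant's count is the number of
items with a positive final code.

**Context decoding (searchlight MVPA).** Imagery-period volumes are shifted by
a fixed 5-TR hemodynamic lag, temporally averaged per trial, and a linear
c-SVC (cost 1) is trained at every voxel on the sphere of radius 4 voxels
around it, with leave-one-run-out cross-validation and seeded label balancing
of the training folds. The per-voxel cross-validated accuracy map is
thresholded to the participant's top 2000 voxels.

**Reinstatement fidelity (RSA).** Within that mask, valid imagery patterns are
averaged per context into a reinstatement template `t_c`. Each covert-recall
pattern `x` is scored by Pearson correlation with the template of the probed
word's learning context, Fisher transformed,

```
z = atanh( r(x, t_c) ),
```

and a within-participant mean split labels trials high- vs low-fidelity.

**Statistics.** Presence scores (1–5) are mean-split; one-week retention is
analysed with a Type III group × presence between-subjects ANOVA with simple
main effects, and recall with univariate mixed repeated-measures ANOVAs
(time × congruency × fidelity × presence, all two-level), reporting partial
eta squared `η²p = SS_effect / (SS_effect + SS_error)`.

## Worked example

```python
from contextmem.pipeline import PipelineConfig, run_full_pipeline

report = run_full_pipeline(PipelineConfig(seed=42, out_dir="results"))
print(report["behavior"]["retention_by_cell"])
print(report["behavior"]["intrusion_mean_by_group"])
print(report["behavior"]["congruency_effect"])
print(report["fmri"]["mean_accuracy_in_signal"])
```

prints (about a minute on one CPU):

```
{'dual_high': 0.896367, 'dual_low': 0.846735, 'single_high': 0.693586, 'single_low': 0.802118}
{'dual': 3.916667, 'single': 6.958333}
0.040527
1.0
```

Reading this: the simulated dual-context / high-presence cell retains ~90% of
its one-week information versus ~69% for single-context / high-presence (the
planted cell means are 0.92 and 0.76; a 48-participant cohort wobbles around
them), dual-context learners intrude roughly 4 items versus 7, congruent
reinstatement cues add ~4 points of recall (planted: 5), and the searchlight
decodes the imagined context perfectly inside the planted signal blobs. The
run also writes `results/` with the cohort tables, NIfTI volumes, accuracy
map, feature mask, fidelity records, ANOVA tables, and `report.json`.

The same stages are available from the shell:

```bash
contextmem run-all --seed 42 --out results/
contextmem simulate-fmri --seed 7 --out bold/
contextmem searchlight --bold bold/ --radius 4 --top-k 2000 --seed 7 --out sl/
```

## Layout

| module | role |
| --- | --- |
| `contextmem.study_design` | two-language / two-context word design, 80-trial test schedule |
| `contextmem.synthetic_data` | behavioural cohort and 4D BOLD-like generators with ground truth |
| `contextmem.recall_scoring` | phoneme scoring, drop rule, forgetting/retention, intrusions |
| `contextmem.pattern_extraction` | HDR-shifted, temporally averaged trial patterns |
| `contextmem.searchlight_mvpa` | sphere-wise linear-SVM decoding, top-K selection |
| `contextmem.rsa_fidelity` | context templates, Fisher-z fidelity, mean split |
| `contextmem.stats_analysis` | presence split, Type III and mixed factorial ANOVA |
| `contextmem.pipeline` / `contextmem.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the modelling choices, generator calibration, and
known limitations.
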