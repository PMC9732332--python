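# Methods

This note documents the models implemented in `contextmem`, the calibration
of the synthetic-data generator, the numerical conventions, and the design
choices made where the underlying study description left the design open.

## Study design

Two languages (L1, L2) are learnt across two virtual contexts (A, B), each
with nine named rooms. A *dual-context* assignment maps each language to its
own context; a *single-context* assignment maps both to context A, leaving B
encoded but linguistically unused. The default word design has 80 items:
10 L1-only, 10 L2-only, and 30 English words learnt in both languages (one
item per language). English glosses and pseudo-foreign transliterations are
deterministic CV-syllable strings generated from the seed; an item's phoneme
count is its transliteration's phoneme count (4–8). Real word lists are not
bundled; nothing downstream depends on lexical content, only on counts and
identities.

The short-delay test schedule probes each item exactly once across 80 trials
in 10 runs of 8. The congruent/incongruent ratio of reinstatement cues is not
pinned down by the design description beyond "pseudo-randomly intermixed"; we
fix it at 50/50 overall *and* per language (20/20), with seeded global
shuffling, because the factorial recall analysis needs near-balanced cells.
Cued rooms are drawn uniformly from the cued context's nine rooms. Whether
congruency was additionally balanced within run is unknown; we balance only
overall, so individual runs may be uneven.

## Behavioural generator

Defaults are the reported cohort-level constants of the design this package
models; each is a `BehaviorSimParams` field.

| parameter | default | meaning |
| --- | --- | --- |
| `n_per_group` | 24 | participants per context group |
| `presence_mean`, `presence_sd` | 3.0, 0.8 | presence scores, truncated normal on [1, 5] |
| `retention_cells` | dual/high 0.92 ± 0.07, single/high 0.76 ± 0.12, both low cells 0.79 ± 0.10 | planted one-week retention mean ± between-subject sd per group × presence cell |
| `t4_base_rate` | 0.48 | short-delay full-recall probability at the congruency midpoint |
| `congruency_boost` | 0.05 | congruent-minus-incongruent recall fraction |
| `partial_noise` | Beta(2, 38) | phoneme-error share on successfully recalled words (mean 5%) |
| `intrusion_rate` | dual 4.09, single 6.57 | Poisson mean intrusion counts |
| `vividness_fail_rate` | 0.08 | probability of an "unsuccessful" imagery rating (4) |
| `scorer_disagree_rate` | 0.10 | probability the second scorer differs by one phoneme |

Presence has no reported distribution; the 3.0 ± 0.8 truncated normal puts
roughly half of each group on each side of a mean split, which is the regime
the presence analysis assumes. A participant's planted retention is drawn
from their group × presence cell (presence cell assigned against the
population mean) and clipped to [0, 1].

Per word: recall at T1–T3 is Bernoulli with probabilities from a saturating
learning curve `p_k = A(1 − e^{−λk})`, `A = 0.55`, with λ calibrated so the
cohort-mean T2 score is 0.42 (the reported two-exposure recall rate); T4 is
Bernoulli with logit `logit(0.48) ± b/2`, where `b = boost / (p(1−p))`
converts the 0.05 recall-fraction boost to the logit scale; every successful
recall is degraded by a Beta partial-phoneme error. Recall indicators are
independent across time points given the curve — the generator does not model
per-word ability correlations, so it understates between-word variance within
participant; the cell-level structure the statistics consume is unaffected.

**One-week degradation.** T5 multiplies the T4 score by a retained share *d*:
with probability `q = 2μ − 1` the word survives intact (`d = 1`), otherwise
`d ~ Uniform(0, 1)` (for a cell mean μ ≥ ½; below that, `d ~ Uniform(0, 2μ)`).
This is the simplest mechanism whose expected retention score equals the
planted μ exactly, which is what makes the cell-mean recovery tests sharp.
Note that "retain fully w.p. μ, else uniform loss" would *not* have this
property (its expectation is `1 − (1−μ)/2`).

Scorer disagreement moves the second scorer by ±1 phoneme with probability
0.1, suppressed at the score boundaries so the two-scorer average stays
unbiased. Intrusions pick `k ~ Poisson(rate)` items with severities 1–3; the
second scorer occasionally under-codes, so the max rule exactly recovers the
planted count.

## 4D generator

Geometry: a 16×16×16 grid (full-volume brain mask), 10 runs × 330 volumes,
TR = 1 s, 8 trials per run on a fixed 40-s period template (ready 1 s, cue
2 s, imagery 10 s, gap 2 s, language cue 3 s, covert recall 8 s, verbal 7 s,
rating 2 s, arithmetic 5 s). The covert-recall ("language") window runs from
the language-cue onset to 6 s later. Signal voxels are two radius-2 blobs
(33 voxels each); each context gets an independent standard-normal template
over them.

Imagery volumes of a trial cued with context *c* are
`baseline + δ·template_c + N(0, σ²)` on signal voxels (noise everywhere
else); covert-recall volumes carry `ρ_t·δ·template` of the probed word's
*learning* context, with per-trial planted fidelity `ρ_t ~ Beta(2, 2)`.
Recall success is `Bernoulli(logit⁻¹(γ0 + γ1 ρ_t))`.

**No HRF convolution.** The planted signal occupies exactly the 5-TR-shifted
windows that the extractor reads; the events table carries unshifted onsets.
This makes extraction exactly self-consistent and keeps the generative model
transparent; the cost is that no HRF-shape or lag mis-specification can be
studied with this generator. Imagery duration is fixed at 10 s even though
real imagery periods are response-timed; the events file carries explicit
onsets and offsets, so the extractor never assumes fixed length.

**SNR calibration** (`separation` δ = 1.5, `noise_sd` σ = 2.0). After
averaging the 10-volume imagery window the effective voxel noise is
σ/√10 ≈ 0.63 against a typical between-context signal difference of
δ·√2 ≈ 2.1 per signal voxel, so spheres containing the blobs are cleanly
separable (near-ceiling decoding) while signal-free spheres stay at chance.
For fidelity, the 6-volume recall window gives
`r ≈ ρ δ² n_sig / (sd_pattern · sd_template) ≈ 0.3 ρ` over a 2000-voxel mask
with n_sig = 66, so the trial-to-trial spread of true r (≈ 0.07) dominates
the r sampling noise (≈ 1/√2000 ≈ 0.022) and Fisher-z fidelity ranks trials
essentially as ρ does. These two defaults were fixed from this arithmetic so
that the planted-signal recovery properties are well-posed at desk scale.

**Fidelity→recall link** (γ0 = logit(0.48) − 0.3, γ1 = 0.6). With
ρ ~ Beta(2, 2), the high/low mean-split halves differ in mean ρ by ≈ 0.36;
a logistic slope of 0.6 at a 0.48 base rate converts this to a recall
difference of `0.36 · 0.6 · p(1−p) ≈ 0.05`, the reported high-vs-low recall
gap (0.50 vs 0.45), and the implied base rate matches the reported short-delay
recall. One-week degradation of the scanner cohort uses μ = 0.90
(dual-context participants with no presence split measured in-scanner).

## Pattern extraction

Windows are half-open volume ranges `[floor(onset/TR) + lag,
floor(offset/TR) + lag)` with lag = 5 TRs added to both ends, truncated to
the run; a window that truncates to empty marks the event invalid rather
than raising. Patterns are per-voxel arithmetic means over the window,
restricted to the brain mask in canonical C-order — the same ordering for
every pattern of a participant. No per-run z-scoring or other normalisation
is applied: downstream correlation and margin-based classification are
location/scale tolerant, and adding an unreported normalisation would change
the fidelity scores. Imagery trials rated unsuccessful (vividness 4) or
lacking rotation button presses are invalid; a trial's language pattern
inherits its imagery validity so that templates and the fidelity scored
against them exclude the same trials. Indexing is 0-based voxel space
throughout; NIfTI affines are written as identity and ignored.

## Searchlight

Spheres are Euclidean in voxel units (`d ≤ r`, r = 4 → 257 voxels in the
interior), clipped at volume and mask boundaries; all in-mask centers are
mapped, including heavily clipped edge spheres. The classifier is the libsvm
c-SVC with a linear kernel and cost 1, no probability calibration, inputs in
canonical trial order. Cross-validation is leave-one-run-out; "repeated over
10 iterations (one for each run)" is read as the 10 folds themselves, with a
`n_balance_repeats` option exposing the alternative reading (multiple
re-balancing draws per fold, averaged). Balancing subsamples only the
training folds — test folds keep all valid trials. A training fold that loses
a class is skipped with a warning; if every fold is skipped the center voxel
is undefined (NaN) and excluded from top-K selection. Top-K ties at the
cutoff break by ascending linear voxel index, which makes feature masks
reproducible bit-for-bit.

## RSA fidelity

Templates average all valid imagery trials of a context within the feature
mask, including the trial whose language pattern is being scored (no
leave-one-out; the same-trial imagery and language periods are different
windows, and the design description implies a single template per context).
Pearson r is clamped to ±(1 − 10⁻⁷) before `atanh`, since noiseless synthetic
data can reach |r| = 1 where the Fisher transform diverges. The high/low
split is a mean split over the participant's own z-values pooled across
congruency conditions, with ties assigned low — deterministic, and
conservative for the high-fidelity advantage. Cells of the
fidelity × time × congruency recall table with no trials are flagged, never
imputed.

## Statistics

Mean splits (presence, fidelity) assign scores equal to the threshold to
"low". The between-subjects group × presence ANOVA uses Type III sums of
squares (mean splits rarely give equal cells); simple main effects of group
within each presence level are tested against the pooled residual. The
repeated-measures designs are analysed as univariate mixed ANOVAs on
per-subject cell means. Because every factor has two levels, each
within-subject effect is exactly a per-subject contrast score, and its F test
with the effect × subject error term equals the Type III test of that
contrast's intercept in a between-subjects regression; interactions with
between factors are the between-factor terms of the same regression. This
reproduces the univariate output of standard commercial mixed-ANOVA
implementations (verified against pingouin on balanced designs), extends to
the 2×2×2×2 design, and needs no sphericity correction (all within effects
have one numerator df). Under unbalanced groups the within-effect tests are
unweighted-means (Type III) tests, which can differ from weighted
(Type I/II) decompositions. Subjects missing any within cell are dropped
with a warning. Effect sizes are partial eta squared.

## Test strategy and what passing shows

The generator is the ground-truth oracle: recovery tests assert that the
pipeline finds exactly the structure planted (cell retention means within
2·sd/√n over 100 cohorts, chance-level maps on signal-free data,
near-ceiling decoding inside blobs, Spearman > 0.5 between planted and
estimated fidelity over 20 seeds, nominal type-I error for both ANOVA
paths). Tiny-instance oracles check numerics independently: brute-force
sphere enumeration, fold-by-fold SVC enumeration, per-voxel loop averaging,
hand sums-of-squares, the paired-t identity F = t². The acceptance suite
uses reduced problem sizes where the full geometry is not the point
(6³ grids for null calibration, 12³ for the 20-seed fidelity loop, with a
signal-plus-random feature mask standing in for top-K selection, which the
full 16³ searchlight → top-2000 → RSA chain covers once).

Passing these tests shows the implementation is faithful to its own model.
It does not show robustness to what the generator omits: autocorrelated and
non-Gaussian fMRI noise, motion and physiological artefacts, HRF variability,
response-timed imagery windows, per-word ability correlations, or scorer
biases beyond symmetric ±1 phoneme disagreement. Real-data use would also
need preprocessing (motion correction, registration, high-pass filtering),
which is deliberately out of scope — the package consumes preprocessed runs.

## Known limitations

- The behavioural and fMRI arms are simulated independently; no participant
  has both a behavioural-cohort row and a 4D dataset.
- The mixed ANOVA requires two-level factors (the designs it serves are all
  2×2×…); k-level within factors would need a different error decomposition.
- `load_fmri_dataset` assumes TR = 1 s when reading back a written dataset;
  pass the TR explicitly when working with other protocols.
- Intrusion severity uses a fixed 0–3 ordinal scale (none / possible /
  probable / definite); the original fine-grained codebook is not public.
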