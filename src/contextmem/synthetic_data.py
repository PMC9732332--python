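"""Synthetic cohorts and small 4D BOLD-like datasets with known ground truth.

No public dataset accompanies the study design this package analyses, so this
module emulates both arms of it:

* a behavioural cohort with a planted group x presence retention structure,
  a congruent-reinstatement recall advantage, group-specific intrusion rates,
  and two noisy scorers per word; and
* per-run 4D volumes in which each trial's imagery period carries a
  context-specific multivariate pattern and each covert-recall period carries
  that pattern scaled by a planted per-trial reinstatement fidelity, which in
  turn drives recall success through a logistic link.

Every generated dataset is paired with a :class:`SyntheticGroundTruth` so that
downstream recovery tests can compare estimates against planted values.  The
planted fMRI signal occupies exactly the hemodynamically shifted windows that
the extractor reads (no HRF convolution); the events table carries unshifted
onsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pattern_extraction import hdr_window
from .study_design import (
    GroupAssignment,
    T4TrialSpec,
    VRContext,
    WordItem,
    build_t4_schedule,
    schedule_to_table,
)

__all__ = [
    "BehaviorSimParams",
    "FmriSimParams",
    "SyntheticGroundTruth",
    "CohortDataset",
    "FmriDataset",
    "simulate_cohort",
    "simulate_fmri",
    "write_dataset",
    "load_fmri_dataset",
]


@dataclass(frozen=True)
class BehaviorSimParams:
    """Calibration of the behavioural cohort generator.

    Cell retention means/sds and the intrusion rates default to the reported
    human cohort values (dual/high-presence 0.92 +- 0.07, single/high 0.76 +-
    0.12, both low-presence cells 0.79 +- 0.10; Poisson intrusion means 4.09
    dual vs 6.57 single); the short-delay base recall rate is 0.48 with a
    +0.05 congruent-reinstatement advantage.
    """

    n_per_group: int = 24
    presence_mean: float = 3.0
    presence_sd: float = 0.8
    retention_cells: dict = field(
        default_factory=lambda: {
            ("dual", "high"): (0.92, 0.07),
            ("single", "high"): (0.76, 0.12),
            ("dual", "low"): (0.79, 0.10),
            ("single", "low"): (0.79, 0.10),
        }
    )
    t4_base_rate: float = 0.48
    congruency_boost: float = 0.05
    partial_noise: tuple[float, float] = (2.0, 38.0)  # Beta(a, b) phoneme-error share
    intrusion_rate: dict = field(
        default_factory=lambda: {"dual": 4.09, "single": 6.57}
    )
    vividness_fail_rate: float = 0.08
    press_missing_rate: float = 0.03
    scorer_disagree_rate: float = 0.10
    learning_curve_max: float = 0.55
    t2_target: float = 0.42  # cohort-mean recall after two exposures

    def __post_init__(self) -> None:
        fracs = [self.t4_base_rate, self.congruency_boost, self.vividness_fail_rate,
                 self.press_missing_rate, self.scorer_disagree_rate, self.t2_target]
        fracs += [m for m, _ in self.retention_cells.values()]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.presence_sd < 0 or any(s < 0 for _, s in self.retention_cells.values()):
            raise ValueError("standard deviations must be non-negative")
        if any(r < 0 for r in self.intrusion_rate.values()):
            raise ValueError("rates must be non-negative")
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")


#: Per-trial period template in seconds; the sum is the trial duration.
DEFAULT_TRIAL_TIMING = {
    "ready": 1.0,
    "reinstatement_cue": 2.0,
    "imagery": 10.0,
    "gap": 2.0,
    "language_cue": 3.0,
    "covert_recall": 8.0,
    "verbal": 7.0,
    "rating": 2.0,
    "arithmetic": 5.0,
}


@dataclass(frozen=True)
class FmriSimParams:
    """Geometry, timing, and signal model of the 4D generator.

    ``separation`` is the amplitude of the context-specific pattern added on
    signal voxels during imagery; the covert-recall pattern is that template
    scaled by the trial's planted fidelity rho.  ``recall_link`` are the
    logistic coefficients (gamma0, gamma1) mapping rho to recall success.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_runs: int = 10
    volumes_per_run: int = 330
    tr_seconds: float = 1.0
    trial_timing: dict = field(default_factory=lambda: dict(DEFAULT_TRIAL_TIMING))
    signal_blobs: tuple = (((4, 8, 8), 2.0), ((11, 8, 8), 2.0))
    separation: float = 1.5
    noise_sd: float = 2.0
    baseline: float = 100.0
    fidelity_dist: tuple[float, float] = (2.0, 2.0)  # Beta(a, b) for rho
    recall_link: tuple[float, float] = (logit(0.48) - 0.3, 0.6)  # (gamma0, gamma1)
    t5_retention: float = 0.90
    partial_noise: tuple[float, float] = (2.0, 38.0)
    vividness_fail_rate: float = 0.08
    press_missing_rate: float = 0.03
    hdr_lag_trs: int = 5

    @property
    def trial_duration(self) -> float:
        return float(sum(self.trial_timing.values()))

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        shape = np.asarray(self.grid_shape)
        for center, radius in self.signal_blobs:
            if np.any(np.asarray(center) - radius < 0) or np.any(np.asarray(center) + radius > shape - 1):
                raise ValueError("signal blobs must lie inside the grid")


@dataclass
class SyntheticGroundTruth:
    """Planted quantities for recovery tests; unused fields stay ``None``."""

    signal_mask: np.ndarray | None = None  # 3D boolean
    context_templates: dict | None = None  # context id -> vector over signal voxels
    planted_fidelity: dict | None = None  # trial_index -> rho
    planted_cell_means: dict | None = None  # (group, presence) -> retention fraction
    planted_recall: dict | None = None  # (item_id, time) -> fraction (cohort means)
    participant_truth: pd.DataFrame | None = None  # per-participant planted values


@dataclass
class CohortDataset:
    participants: pd.DataFrame  # id, group, presence, intrusion counts per scorer
    word_scores: pd.DataFrame  # participant, item_id, time, scorer, n_correct, n_total
    trials: pd.DataFrame  # participant + T4TrialSpec fields + vividness + valid
    intrusions: pd.DataFrame  # participant, item_id, scorer, code


@dataclass
class FmriDataset:
    runs: list  # list of 4D float32 arrays (x, y, z, t)
    mask: np.ndarray  # 3D boolean
    events: pd.DataFrame
    trials: pd.DataFrame  # per-trial planted fidelity, recall scores, validity
    tr_seconds: float
    ground_truth: SyntheticGroundTruth


def _logit_boost(base: float, boost: float) -> float:
    # logit-scale step whose first-order recall-fraction effect equals `boost`
    return boost / (base * (1.0 - base))


def _degrade(t4: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative one-week degradation with E[retained share] = mu.

    With probability q the word survives intact, otherwise a uniform share
    survives; q and the uniform range are set so the expected retention score
    equals the planted cell mean exactly (q = 2*mu - 1 for mu >= 0.5).
    """
    n = t4.shape[0]
    if mu >= 0.5:
        keep = rng.random(n) < (2.0 * mu - 1.0)
        d = np.where(keep, 1.0, rng.uniform(0.0, 1.0, size=n))
    else:
        d = rng.uniform(0.0, 2.0 * mu, size=n)
    return t4 * d


def simulate_cohort(
    params: BehaviorSimParams,
    design: list[WordItem],
    seed: int,
    contexts: tuple[VRContext, VRContext] | None = None,
    n_runs: int = 10,
) -> tuple[CohortDataset, SyntheticGroundTruth]:
    """Simulate a two-group cohort over the given word design.

    ``design`` is the item list of a dual-context build; for single-context
    participants every item's learning context is remapped to Context A.  Each
    participant receives their own seeded test schedule.  Recall at T1-T3
    follows a saturating learning curve calibrated so the cohort-mean score at
    T2 matches ``t2_target``; T4 is Bernoulli full recall (congruency-shifted
    on the logit scale) times a Beta partial-phoneme error; T5 multiplies T4
    by a degradation whose expectation is the participant's planted
    group x presence retention mean.
    """
    if not design:
        raise ValueError("design must be non-empty")
    if contexts is None:
        from .study_design import default_contexts

        contexts = default_contexts()

    rng = np.random.default_rng(seed)
    n_words = len(design)
    phonemes = np.array([w.phoneme_count for w in design])
    item_ids = np.array([w.item_id for w in design])

    # learning-curve full-recall probabilities at T1-T3, calibrated at T2
    e_mean = params.partial_noise[0] / sum(params.partial_noise)
    p2 = min(params.t2_target / (1.0 - e_mean), params.learning_curve_max)
    lam = -0.5 * np.log(1.0 - p2 / params.learning_curve_max)
    p_curve = {
        t: params.learning_curve_max * (1.0 - np.exp(-lam * k))
        for k, t in enumerate(("T1", "T2", "T3"), start=1)
    }

    b = _logit_boost(params.t4_base_rate, params.congruency_boost)
    l0 = logit(params.t4_base_rate)

    part_rows, trial_frames, intrusion_rows = [], [], []
    sc_part, sc_item, sc_time, sc_scorer, sc_nc, sc_nt = [], [], [], [], [], []
    truth_rows = []

    pid = 0
    for group in ("dual", "single"):
        if group == "dual":
            items_g = design
            assignment = GroupAssignment("dual", {"L1": "A", "L2": "B"})
        else:
            items_g = [replace(w, learning_context="A") for w in design]
            assignment = GroupAssignment("single", {"L1": "A", "L2": "A"})
        for _ in range(params.n_per_group):
            pid += 1
            part = f"sub-{pid:03d}"
            presence = float(np.clip(rng.normal(params.presence_mean, params.presence_sd), 1.0, 5.0))
            presence_cell = "high" if presence > params.presence_mean else "low"
            mu_m, mu_s = params.retention_cells[(group, presence_cell)]
            mu = float(np.clip(rng.normal(mu_m, mu_s), 0.0, 1.0))

            schedule = build_t4_schedule(
                items_g, assignment, contexts, n_runs=n_runs,
                seed=int(rng.integers(2**31)),
            )
            congruent = pd.Series(
                {t.probed_item: t.congruency == "congruent" for t in schedule}
            ).reindex(item_ids).to_numpy()

            scores: dict[str, np.ndarray] = {}
            for t in ("T1", "T2", "T3"):
                ind = rng.random(n_words) < p_curve[t]
                scores[t] = ind * (1.0 - rng.beta(*params.partial_noise, size=n_words))
            p4 = expit(l0 + np.where(congruent, 0.5, -0.5) * b)
            ind4 = rng.random(n_words) < p4
            scores["T4"] = ind4 * (1.0 - rng.beta(*params.partial_noise, size=n_words))
            scores["T5"] = _degrade(scores["T4"], mu, rng)

            for t, s in scores.items():
                nc_true = np.rint(s * phonemes).astype(int)
                # +-1 phoneme disagreement, only away from the scale ends so
                # the two-scorer average stays unbiased
                jitter = (2 * rng.integers(0, 2, size=n_words) - 1) * (
                    rng.random(n_words) < params.scorer_disagree_rate
                )
                jitter[(nc_true == 0) | (nc_true == phonemes)] = 0
                nc_b = nc_true + jitter
                for scorer, nc in (("scorer1", nc_true), ("scorer2", nc_b)):
                    sc_part.append(np.repeat(part, n_words))
                    sc_item.append(item_ids)
                    sc_time.append(np.repeat(t, n_words))
                    sc_scorer.append(np.repeat(scorer, n_words))
                    sc_nc.append(nc)
                    sc_nt.append(phonemes)

            k = int(min(rng.poisson(params.intrusion_rate[group]), n_words))
            if k:
                which = rng.choice(n_words, size=k, replace=False)
                sev = rng.integers(1, 4, size=k)
                sev_b = np.where(rng.random(k) < 0.8, sev, np.maximum(sev - 1, 0))
                for i, s1, s2 in zip(which, sev, sev_b):
                    intrusion_rows.append((part, item_ids[i], "scorer1", int(s1)))
                    intrusion_rows.append((part, item_ids[i], "scorer2", int(s2)))

            tf = schedule_to_table(schedule)
            tf.insert(0, "participant", part)
            viv = np.where(
                rng.random(len(tf)) < params.vividness_fail_rate,
                4, rng.integers(1, 4, size=len(tf)),
            )
            tf["vividness"] = viv
            tf["valid"] = rng.random(len(tf)) >= params.press_missing_rate
            trial_frames.append(tf)

            part_rows.append(
                {"participant": part, "group": group, "presence": presence,
                 "intrusion_count_scorer1": k, "intrusion_count_scorer2": k}
            )
            truth_rows.append(
                {"participant": part, "group": group, "presence_cell": presence_cell,
                 "planted_retention": mu, "planted_intrusion_rate": params.intrusion_rate[group]}
            )

    word_scores = pd.DataFrame(
        {
            "participant": np.concatenate(sc_part),
            "item_id": np.concatenate(sc_item),
            "time": np.concatenate(sc_time),
            "scorer": np.concatenate(sc_scorer),
            "n_correct": np.concatenate(sc_nc),
            "n_total": np.concatenate(sc_nt),
        }
    )
    cohort = CohortDataset(
        participants=pd.DataFrame(part_rows),
        word_scores=word_scores,
        trials=pd.concat(trial_frames, ignore_index=True),
        intrusions=pd.DataFrame(
            intrusion_rows, columns=["participant", "item_id", "scorer", "code"]
        ),
    )
    truth = SyntheticGroundTruth(
        planted_cell_means={k: v[0] for k, v in params.retention_cells.items()},
        participant_truth=pd.DataFrame(truth_rows),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# fMRI generator


def _blob_mask(shape: tuple[int, int, int], blobs) -> np.ndarray:
    grids = np.indices(shape)
    mask = np.zeros(shape, dtype=bool)
    for center, radius in blobs:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        mask |= d2 <= radius**2
    return mask


def simulate_fmri(
    params: FmriSimParams,
    schedule: list[T4TrialSpec],
    seed: int,
    learning_context_of: dict[str, str] | None = None,
) -> FmriDataset:
    """Simulate per-run 4D volumes with planted context patterns.

    Imagery-period volumes of a trial cued with context *c* carry ``baseline +
    separation * template_c + noise`` on signal voxels; covert-recall volumes
    carry the probed word's learning-context template scaled by the trial's
    planted fidelity rho.  The signal occupies the HDR-shifted windows so the
    extractor's fixed-lag convention recovers it; the events table is written
    with unshifted onsets.  ``learning_context_of`` maps item_id to learning
    context; by default it is inferred from congruency and the cued context.
    """
    n_trials = len(schedule)
    if n_trials == 0 or n_trials % params.n_runs != 0:
        raise ValueError("schedule length must be divisible by n_runs")
    per_run = n_trials // params.n_runs
    run_secs = params.volumes_per_run * params.tr_seconds
    if per_run * params.trial_duration > run_secs:
        raise ValueError("run overflow")

    rng = np.random.default_rng(seed)
    shape = tuple(params.grid_shape)
    mask = np.ones(shape, dtype=bool)
    signal_mask = _blob_mask(shape, params.signal_blobs)
    sig_idx = np.flatnonzero(signal_mask.ravel())
    templates = {c: rng.standard_normal(sig_idx.size) for c in ("A", "B")}

    if learning_context_of is None:
        learning_context_of = {
            t.probed_item: t.cued_context if t.congruency == "congruent"
            else ("B" if t.cued_context == "A" else "A")
            for t in schedule
        }

    tt = params.trial_timing
    imagery_onset = tt["ready"] + tt["reinstatement_cue"]
    language_onset = imagery_onset + tt["imagery"] + tt["gap"]
    language_dur = 6.0  # covert-recall window: cue onset + 6 s

    gamma0, gamma1 = params.recall_link
    rho = rng.beta(*params.fidelity_dist, size=n_trials)
    success = rng.random(n_trials) < expit(gamma0 + gamma1 * rho)
    t4 = success * (1.0 - rng.beta(*params.partial_noise, size=n_trials))
    t5 = _degrade(t4, params.t5_retention, rng)
    vividness = np.where(
        rng.random(n_trials) < params.vividness_fail_rate,
        4, rng.integers(1, 4, size=n_trials),
    )
    valid = rng.random(n_trials) >= params.press_missing_rate

    runs = [
        (params.baseline + rng.normal(0.0, params.noise_sd,
                                      size=shape + (params.volumes_per_run,))
         ).astype(np.float32)
        for _ in range(params.n_runs)
    ]

    event_rows, trial_rows = [], []
    for t_i, trial in enumerate(schedule):
        run_i = trial.run_index - 1
        pos = (trial.trial_index - 1) % per_run
        start = pos * params.trial_duration
        learn_ctx = learning_context_of[trial.probed_item]
        periods = (
            ("imagery", start + imagery_onset, start + imagery_onset + tt["imagery"],
             trial.cued_context, templates[trial.cued_context], 1.0),
            ("language", start + language_onset, start + language_onset + language_dur,
             learn_ctx, templates[learn_ctx], rho[t_i]),
        )
        flat = runs[run_i].reshape(-1, params.volumes_per_run)
        for period, onset, offset, ctx, template, amp in periods:
            window = hdr_window(onset, offset, params.tr_seconds,
                                params.hdr_lag_trs, params.volumes_per_run)
            if window is not None:
                flat[sig_idx, window.start:window.stop] += (
                    amp * params.separation * template
                )[:, None]
            event_rows.append(
                {"onset": onset, "duration": offset - onset,
                 "run": trial.run_index, "trial": trial.trial_index,
                 "period": period, "context": ctx, "room": trial.cued_room,
                 "item_id": trial.probed_item,
                 "language": trial.probed_item.rsplit("_", 1)[-1],
                 "congruency": trial.congruency,
                 "vividness": int(vividness[t_i]), "valid": bool(valid[t_i])}
            )
        trial_rows.append(
            {"trial": trial.trial_index, "run": trial.run_index,
             "item_id": trial.probed_item, "congruency": trial.congruency,
             "cued_context": trial.cued_context, "learning_context": learn_ctx,
             "planted_fidelity": rho[t_i], "recall_success": bool(success[t_i]),
             "recall_T4": t4[t_i], "recall_T5": t5[t_i],
             "vividness": int(vividness[t_i]), "valid": bool(valid[t_i])}
        )

    truth = SyntheticGroundTruth(
        signal_mask=signal_mask,
        context_templates=templates,
        planted_fidelity={t.trial_index: float(r) for t, r in zip(schedule, rho)},
    )
    return FmriDataset(
        runs=runs, mask=mask, events=pd.DataFrame(event_rows),
        trials=pd.DataFrame(trial_rows), tr_seconds=params.tr_seconds,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# serialisation


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: CohortDataset | FmriDataset, out_dir: str | Path) -> dict:
    """Write a dataset to disk and return a manifest of files with checksums.

    fMRI volumes go out as NIfTI, the events table as tab-separated text,
    behavioural tables as CSV, and ground truth as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    if isinstance(dataset, CohortDataset):
        for name in ("participants", "word_scores", "trials", "intrusions"):
            path = out / f"{name}.csv"
            getattr(dataset, name).to_csv(path, index=False)
            files.append(path)
    elif isinstance(dataset, FmriDataset):
        affine = np.eye(4)
        for i, run in enumerate(dataset.runs, start=1):
            path = out / f"run-{i:02d}_bold.nii.gz"
            nib.save(nib.Nifti1Image(run, affine), path)
            files.append(path)
        path = out / "mask.nii.gz"
        nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), affine), path)
        files.append(path)
        path = out / "events.tsv"
        dataset.events.to_csv(path, sep="\t", index=False)
        files.append(path)
        path = out / "trials.csv"
        dataset.trials.to_csv(path, index=False)
        files.append(path)
        gt = dataset.ground_truth
        payload = {
            "signal_voxels": np.argwhere(gt.signal_mask).tolist(),
            "context_templates": {k: v.tolist() for k, v in gt.context_templates.items()},
            "planted_fidelity": {str(k): v for k, v in gt.planted_fidelity.items()},
        }
        path = out / "ground_truth.json"
        path.write_text(json.dumps(payload, sort_keys=True))
        files.append(path)
    else:
        raise TypeError(f"unsupported dataset type {type(dataset)!r}")

    manifest = {str(p.relative_to(out)): _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def load_fmri_dataset(in_dir: str | Path) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame, float]:
    """Read back runs, mask and events written by :func:`write_dataset`."""
    src = Path(in_dir)
    run_paths = sorted(src.glob("run-*_bold.nii.gz"))
    if not run_paths:
        raise FileNotFoundError(f"no run-*_bold.nii.gz under {src}")
    runs = [np.asarray(nib.load(p).dataobj, dtype=np.float32) for p in run_paths]
    mask = np.asarray(nib.load(src / "mask.nii.gz").dataobj).astype(bool)
    events = pd.read_csv(src / "events.tsv", sep="\t")
    return runs, mask, events, 1.0
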