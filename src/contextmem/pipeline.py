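"""End-to-end orchestration: simulate -> score -> extract -> decode -> RSA -> stats.

The pipeline writes every intermediate to disk under the output directory,
stamps outputs with a hash of the configuration, and produces a deterministic
JSON run report with the headline numbers (cell retention means, intrusion
means, the congruency effect, high/low-fidelity recall means).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pattern_extraction import collect_patterns
from .recall_scoring import participant_summary, reconcile_word_scores
from .rsa_fidelity import build_context_templates, recall_by_fidelity, score_fidelity
from .searchlight_mvpa import SearchlightConfig, run_searchlight, top_k_mask
from .stats_analysis import (
    between_anova_2x2,
    presence_split,
    rm_anova_factorial,
    summarize_cells,
)
from .study_design import build_t4_schedule, build_word_design, default_contexts, schedule_to_table, words_to_table
from .synthetic_data import (
    BehaviorSimParams,
    FmriSimParams,
    simulate_cohort,
    simulate_fmri,
    write_dataset,
)

log = logging.getLogger("contextmem")

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_l1_only: int = 10
    n_l2_only: int = 10
    n_shared: int = 30
    n_runs: int = 10
    swap_contexts: bool = False
    behavior: BehaviorSimParams = field(default_factory=BehaviorSimParams)
    fmri: FmriSimParams = field(default_factory=FmriSimParams)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    run_behavior: bool = True
    run_fmri: bool = True
    out_dir: str = "results"


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # hash the scientific config, not its location
    payload = json.dumps(_stringify_keys(payload), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round(x, nd=6):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


def _anova_rows(results) -> list[dict]:
    return [
        {"effect": r.effect, "F": _round(r.F), "df_num": r.df_num, "df_den": r.df_den,
         "p": _round(r.p), "partial_eta_sq": _round(r.partial_eta_sq)}
        for r in results
    ]


def _behavior_stage(config: PipelineConfig, out: Path, rng: np.random.Generator) -> dict:
    words, _ = build_word_design(
        config.n_l1_only, config.n_l2_only, config.n_shared, "dual",
        seed=int(rng.integers(2**31)),
    )
    contexts = default_contexts(config.swap_contexts)
    words_to_table(words).to_csv(out / "word_design.tsv", sep="\t", index=False)

    cohort, truth = simulate_cohort(
        config.behavior, words, seed=int(rng.integers(2**31)),
        contexts=contexts, n_runs=config.n_runs,
    )
    write_dataset(cohort, out / "behavior")

    summary = participant_summary(cohort.word_scores, cohort.intrusions)
    summary = summary.merge(cohort.participants[["participant", "group", "presence"]], on="participant")
    split = presence_split(summary.set_index("participant")["presence"])
    summary["presence_cell"] = summary["participant"].map(split.assignment)
    summary.to_csv(out / "participant_summary.csv", index=False)

    retention = summary.dropna(subset=["one_week_retention"])
    filled = retention.groupby(["group", "presence_cell"]).size()
    if len(filled) == 4 and (filled > 0).all():
        anova = between_anova_2x2(
            retention["one_week_retention"], retention["group"], retention["presence_cell"]
        )
    else:
        log.warning("between ANOVA skipped: empty group x presence cell")
        anova = []

    # congruency effect on short-delay recall, within-subject
    scores = reconcile_word_scores(cohort.word_scores)
    t4 = scores[scores["time"] == "T4"].merge(
        cohort.trials[["participant", "probed_item", "congruency"]],
        left_on=["participant", "item_id"], right_on=["participant", "probed_item"],
    )
    cong_anova = rm_anova_factorial(t4, dv="score", subject="participant", within=["congruency"])
    cong_means = t4.groupby("congruency")["score"].mean()

    cells = summarize_cells(
        summary, ["group", "presence_cell"],
        ["one_week_retention", "recall_T4", "intrusion_count"],
    )
    cells.to_csv(out / "cell_summary.csv", index=False)
    pd.DataFrame(_anova_rows(anova + cong_anova)).to_csv(out / "behavior_anova.csv", index=False)

    cell_retention = {
        f"{g}_{p}": _round(m)
        for g, p, m in zip(cells["group"], cells["presence_cell"], cells["one_week_retention_mean"])
    }
    intrusion_means = summary.groupby("group")["intrusion_count"].mean()
    return {
        "retention_by_cell": cell_retention,
        "intrusion_mean_by_group": {k: _round(v) for k, v in intrusion_means.items()},
        "congruency_recall_means": {k: _round(v) for k, v in cong_means.items()},
        "congruency_effect": _round(cong_means.get("congruent", np.nan) - cong_means.get("incongruent", np.nan)),
        "anova": _anova_rows(anova + cong_anova),
    }


def _fmri_stage(config: PipelineConfig, out: Path, rng: np.random.Generator) -> dict:
    words, assignment = build_word_design(
        config.n_l1_only, config.n_l2_only, config.n_shared, "dual",
        seed=int(rng.integers(2**31)),
    )
    contexts = default_contexts(config.swap_contexts)
    schedule = build_t4_schedule(words, assignment, contexts, config.n_runs,
                                 seed=int(rng.integers(2**31)))
    schedule_to_table(schedule).to_csv(out / "t4_schedule.tsv", sep="\t", index=False)

    dataset = simulate_fmri(config.fmri, schedule, seed=int(rng.integers(2**31)))
    write_dataset(dataset, out / "fmri")

    patterns = collect_patterns(dataset.runs, dataset.mask, dataset.events,
                                dataset.tr_seconds, config.fmri.hdr_lag_trs)
    X_img, meta_img = patterns.matrix("imagery")
    acc_map = run_searchlight(X_img, meta_img["label"], meta_img["run"],
                              dataset.mask, config.searchlight)
    feature_mask = top_k_mask(acc_map, config.searchlight.top_k)

    import nibabel as nib

    nib.save(nib.Nifti1Image(np.nan_to_num(acc_map, nan=-1.0), np.eye(4)),
             out / "searchlight_accuracy.nii.gz")
    nib.save(nib.Nifti1Image(feature_mask.astype(np.uint8), np.eye(4)),
             out / "feature_mask.nii.gz")

    feature_cols = np.searchsorted(patterns.voxel_index, np.flatnonzero(feature_mask.ravel()))
    templates = build_context_templates(X_img, meta_img["label"].to_numpy(), feature_cols)
    X_lang, meta_lang = patterns.matrix("language")
    fidelity = score_fidelity(X_lang, meta_lang, templates, feature_cols, dataset.trials)
    fidelity.to_csv(out / "fidelity_records.csv", index=False)
    cells = recall_by_fidelity(fidelity)
    cells.to_csv(out / "recall_by_fidelity.csv", index=False)

    long = fidelity.melt(
        id_vars=["trial", "fidelity_class", "congruency"],
        value_vars=["recall_T4", "recall_T5"], var_name="time", value_name="recall",
    )
    # single synthetic participant: report cell means; the factorial test needs a cohort
    by_class = long.groupby("fidelity_class")["recall"].mean()
    in_mask_acc = float(np.nanmean(acc_map[dataset.ground_truth.signal_mask])) \
        if dataset.ground_truth.signal_mask is not None else None
    return {
        "mean_accuracy": _round(float(np.nanmean(acc_map))),
        "mean_accuracy_in_signal": _round(in_mask_acc),
        "recall_by_fidelity": {k: _round(v) for k, v in by_class.items()},
        "fidelity_effect": _round(by_class.get("high", np.nan) - by_class.get("low", np.nan)),
        "n_valid_recall_trials": int(len(fidelity)),
    }


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return (and write) the run report."""
    out = Path(config.out_dir)
    cfg_hash = _config_hash(config)
    marker = out / "config_hash.txt"
    if marker.exists() and marker.read_text().strip() != cfg_hash:
        raise RuntimeError(
            f"output directory {out} holds results for a different configuration; "
            "choose a fresh directory or delete it explicitly"
        )
    out.mkdir(parents=True, exist_ok=True)
    marker.write_text(cfg_hash)

    rng = np.random.default_rng(config.seed)
    report: dict = {
        "version": __version__, "seed": config.seed, "config_hash": cfg_hash,
        "stages": {},
    }
    behavior_rng = np.random.default_rng(rng.integers(2**31))
    fmri_rng = np.random.default_rng(rng.integers(2**31))
    if config.run_behavior:
        log.info("stage behavior: simulating and scoring cohort")
        report["behavior"] = _behavior_stage(config, out, behavior_rng)
        report["stages"]["behavior"] = "ok"
    else:
        report["stages"]["behavior"] = "skipped"
    if config.run_fmri:
        log.info("stage fmri: simulate, extract, searchlight, rsa")
        report["fmri"] = _fmri_stage(config, out, fmri_rng)
        report["stages"]["fmri"] = "ok"
    else:
        report["stages"]["fmri"] = "skipped"

    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
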