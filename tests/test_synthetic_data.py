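"""Cohort and 4D generators: planted structure, ground truth, serialisation."""

import json

import numpy as np
import pandas as pd
import pytest

from contextmem.pattern_extraction import collect_patterns
from contextmem.recall_scoring import intrusion_summary, participant_summary
from contextmem.rsa_fidelity import build_context_templates, fidelity_score
from contextmem.synthetic_data import (
    BehaviorSimParams,
    FmriSimParams,
    load_fmri_dataset,
    simulate_cohort,
    simulate_fmri,
    write_dataset,
)
from tests.conftest import small_fmri_params


class TestSimulateCohort:
    def test_cohort_size_echoes_config(self, design):
        words, _ = design
        cohort, _ = simulate_cohort(BehaviorSimParams(n_per_group=24), words, seed=0)
        assert len(cohort.participants) == 48
        assert cohort.participants["group"].value_counts().to_dict() == {
            "dual": 24, "single": 24,
        }

    def test_invalid_params_rejected(self, design):
        with pytest.raises(ValueError):
            BehaviorSimParams(n_per_group=0)
        with pytest.raises(ValueError):
            BehaviorSimParams(t4_base_rate=1.2)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(BehaviorSimParams(), [], seed=0)

    def test_scores_within_bounds(self, design):
        words, _ = design
        cohort, _ = simulate_cohort(BehaviorSimParams(n_per_group=4), words, seed=1)
        ws = cohort.word_scores
        assert (ws["n_correct"] >= 0).all()
        assert (ws["n_correct"] <= ws["n_total"]).all()
        assert set(cohort.trials["vividness"]) <= {1, 2, 3, 4}

    def test_noiseless_cells_hit_planted_retention(self, design):
        """All variability off: pipeline retention per cell equals the planted
        mean up to Monte-Carlo error of the degradation draw."""
        words, _ = design
        params = BehaviorSimParams(
            n_per_group=40, presence_sd=0.0, scorer_disagree_rate=0.0,
            partial_noise=(1e-6, 1.0), vividness_fail_rate=0.0,
            retention_cells={(g, p): (0.92, 0.0) for g in ("dual", "single")
                             for p in ("high", "low")},
        )
        cohort, truth = simulate_cohort(params, words, seed=7)
        summary = participant_summary(cohort.word_scores)
        assert summary["one_week_retention"].mean() == pytest.approx(0.92, abs=0.015)
        # T4 full-recall words are scored exactly 1 in the noiseless limit
        t4 = cohort.word_scores.query("time == 'T4' and n_correct > 0")
        assert (t4["n_correct"] == t4["n_total"]).all()

    def test_intrusion_counts_consistent_with_max_rule(self, design):
        words, _ = design
        cohort, _ = simulate_cohort(BehaviorSimParams(n_per_group=8), words, seed=3)
        counts = intrusion_summary(cohort.intrusions)
        planted = cohort.participants.set_index("participant")["intrusion_count_scorer1"]
        aligned = counts.reindex(planted.index).fillna(0).astype(int)
        assert (aligned == planted).all()

    def test_congruency_boost_recovered_at_scale(self, design):
        words, _ = design
        params = BehaviorSimParams(n_per_group=60, partial_noise=(1e-6, 1.0),
                                   scorer_disagree_rate=0.0)
        cohort, _ = simulate_cohort(params, words, seed=11)
        from contextmem.recall_scoring import reconcile_word_scores

        t4 = reconcile_word_scores(cohort.word_scores).query("time == 'T4'").merge(
            cohort.trials[["participant", "probed_item", "congruency"]],
            left_on=["participant", "item_id"], right_on=["participant", "probed_item"],
        )
        means = t4.groupby("congruency")["score"].mean()
        assert means["congruent"] - means["incongruent"] == pytest.approx(0.05, abs=0.02)

    def test_ground_truth_carries_cell_means(self, design):
        words, _ = design
        _, truth = simulate_cohort(BehaviorSimParams(n_per_group=2), words, seed=0)
        assert truth.planted_cell_means[("dual", "high")] == 0.92
        assert truth.planted_cell_means[("single", "high")] == 0.76


class TestSimulateFmri:
    def test_default_dimensions(self, fmri_default):
        assert len(fmri_default.runs) == 10
        assert all(r.shape == (16, 16, 16, 330) for r in fmri_default.runs)
        assert fmri_default.mask.shape == (16, 16, 16)

    def test_events_one_imagery_one_language_per_trial(self, fmri_default):
        ev = fmri_default.events
        per_trial = ev.groupby("trial")["period"].value_counts().unstack()
        assert (per_trial["imagery"] == 1).all()
        assert (per_trial["language"] == 1).all()
        run_end = 330 * fmri_default.tr_seconds
        assert ((ev["onset"] >= 0) & (ev["onset"] + ev["duration"] <= run_end)).all()

    def test_run_overflow_rejected(self, schedule):
        timing = dict(FmriSimParams().trial_timing)
        timing["imagery"] = 60.0
        with pytest.raises(ValueError, match="run overflow"):
            simulate_fmri(small_fmri_params(trial_timing=timing,
                                            volumes_per_run=100), schedule, seed=0)

    def test_blob_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="inside the grid"):
            FmriSimParams(grid_shape=(8, 8, 8))  # default blobs need 16^3

    def test_noiseless_full_fidelity_gives_r_one(self, schedule):
        """sigma = 0 and rho = 1: the recall-period pattern on signal voxels is
        exactly the context template, so downstream Pearson r = 1."""
        params = small_fmri_params(
            noise_sd=0.0, fidelity_dist=(1e9, 1e-3), vividness_fail_rate=0.0,
            press_missing_rate=0.0,
        )
        ds = simulate_fmri(params, schedule, seed=2)
        ps = collect_patterns(ds.runs, ds.mask, ds.events, ds.tr_seconds)
        Xi, mi = ps.matrix("imagery")
        sig = np.searchsorted(ps.voxel_index,
                              np.flatnonzero(ds.ground_truth.signal_mask.ravel()))
        templates = build_context_templates(Xi, mi["label"].to_numpy(), sig)
        Xl, ml = ps.matrix("language")
        r, z = fidelity_score(Xl[0][sig], templates[str(ml["label"].iloc[0])])
        assert r == pytest.approx(1.0, abs=1e-5)
        assert np.isfinite(z)

    def test_planted_fidelity_in_unit_interval(self, fmri_default):
        rho = np.array(list(fmri_default.ground_truth.planted_fidelity.values()))
        assert rho.min() >= 0.0 and rho.max() <= 1.0
        assert len(rho) == 80


class TestWriteDataset:
    def test_cohort_roundtrip_tables(self, design, tmp_path):
        words, _ = design
        cohort, _ = simulate_cohort(BehaviorSimParams(n_per_group=2), words, seed=0)
        write_dataset(cohort, tmp_path)
        back = pd.read_csv(tmp_path / "word_scores.csv")
        pd.testing.assert_frame_equal(back, cohort.word_scores)

    def test_fmri_file_inventory_and_roundtrip(self, schedule, tmp_path):
        params = small_fmri_params(volumes_per_run=330)
        ds = simulate_fmri(params, schedule, seed=1)
        manifest = write_dataset(ds, tmp_path)
        assert sum(k.startswith("run-") for k in manifest) == 10
        assert {"mask.nii.gz", "events.tsv", "ground_truth.json"} <= set(manifest)
        runs, mask, events, _ = load_fmri_dataset(tmp_path)
        assert np.allclose(runs[0], ds.runs[0])
        assert np.array_equal(mask, ds.mask)
        pd.testing.assert_frame_equal(events, ds.events, check_dtype=False)

    def test_checksum_changes_iff_content_changes(self, design, tmp_path):
        words, _ = design
        cohort, _ = simulate_cohort(BehaviorSimParams(n_per_group=2), words, seed=0)
        m1 = write_dataset(cohort, tmp_path / "a")
        m2 = write_dataset(cohort, tmp_path / "b")
        assert m1 == m2
        (tmp_path / "b" / "participants.csv").write_text("tampered")
        m3 = write_dataset(cohort, tmp_path / "a")  # rewrite, unchanged content
        assert m3["participants.csv"] == m1["participants.csv"]
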