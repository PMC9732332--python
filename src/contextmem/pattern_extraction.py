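"""From 4D runs plus an events table to one voxel-pattern vector per trial period.

Event onsets/offsets are shifted by a fixed hemodynamic lag (default 5 TRs,
added to both ends), converted to a half-open volume window, truncated to the
run, and the run's timeseries is temporally averaged over that window at each
in-mask voxel.  Imagery periods are invalidated when the participant rated the
reinstatement unsuccessful (vividness 4) or failed to report rotation progress
via button presses; a trial's covert-recall (language) pattern inherits its
imagery validity.  Voxel ordering is the canonical C-order scan of the brain
mask and is identical across every pattern of a participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrialPattern", "PatternSet", "hdr_window", "extract_trial_pattern", "collect_patterns"]

DEFAULT_HDR_LAG_TRS = 5


@dataclass(frozen=True)
class TrialPattern:
    trial_index: int
    period: str  # "imagery" | "language"
    label: str  # context id (imagery) or learning-context of the probed word
    run_index: int
    item_id: str | None
    vector: np.ndarray | None  # None when the window truncated to empty
    valid: bool


@dataclass
class PatternSet:
    """All trial patterns of a participant with a shared voxel ordering."""

    patterns: list[TrialPattern]
    voxel_index: np.ndarray  # flat indices of in-mask voxels, canonical order

    def matrix(self, period: str, valid_only: bool = True):
        """(trials x voxels) matrix plus aligned labels / runs / trial indices."""
        sel = [
            p for p in self.patterns
            if p.period == period and p.vector is not None and (p.valid or not valid_only)
        ]
        if not sel:
            raise ValueError(f"no usable {period} patterns")
        X = np.vstack([p.vector for p in sel])
        meta = pd.DataFrame(
            {
                "trial": [p.trial_index for p in sel],
                "label": [p.label for p in sel],
                "run": [p.run_index for p in sel],
                "item_id": [p.item_id for p in sel],
            }
        )
        return X, meta


def hdr_window(
    onset_seconds: float,
    offset_seconds: float,
    tr_seconds: float,
    lag_trs: int = DEFAULT_HDR_LAG_TRS,
    run_length_volumes: int = 0,
) -> range | None:
    """Half-open volume range for a period after the hemodynamic-lag shift.

    Returns ``[floor(onset/tr) + lag, floor(offset/tr) + lag)`` truncated to
    ``[0, run_length_volumes)``; ``None`` when truncation leaves it empty.
    """
    if onset_seconds >= offset_seconds:
        raise ValueError("onset must precede offset")
    if lag_trs < 0:
        raise ValueError("lag_trs must be non-negative")
    lo = int(np.floor(onset_seconds / tr_seconds)) + lag_trs
    hi = int(np.floor(offset_seconds / tr_seconds)) + lag_trs
    lo = max(lo, 0)
    hi = min(hi, run_length_volumes)
    if lo >= hi:
        return None
    return range(lo, hi)


def extract_trial_pattern(
    run_data: np.ndarray, brain_mask: np.ndarray, window: range | None
) -> np.ndarray:
    """Temporal mean over the window at each in-mask voxel, canonical order."""
    if window is None or len(window) == 0:
        raise ValueError("invalid window")
    if run_data.shape[:3] != brain_mask.shape:
        raise ValueError("mask shape must match the run's spatial shape")
    if window.start < 0 or window.stop > run_data.shape[3]:
        raise ValueError("window exceeds run bounds")
    segment = run_data[..., window.start:window.stop]
    return segment.mean(axis=3, dtype=np.float64)[brain_mask]


def collect_patterns(
    runs: list[np.ndarray],
    brain_mask: np.ndarray,
    events: pd.DataFrame,
    tr_seconds: float = 1.0,
    lag_trs: int = DEFAULT_HDR_LAG_TRS,
) -> PatternSet:
    """One labelled pattern per period event, with validity flags applied.

    ``events`` uses the tab-separated dialect of the synthetic generator:
    columns ``onset, duration, run, trial, period, context, item_id,
    vividness, valid`` (1-based run indices).  Events whose window survives
    truncation yield a vector; events off the end of their run raise.
    """
    n_runs = len(runs)
    run_len = {i + 1: runs[i].shape[3] for i in range(n_runs)}
    bad = events[(events["run"] < 1) | (events["run"] > n_runs)]
    if len(bad):
        raise ValueError(f"events reference missing runs for trials {sorted(bad['trial'])}")
    out_of_run = events[
        events["onset"] >= events["run"].map(run_len) * tr_seconds
    ]
    if len(out_of_run):
        raise ValueError(
            f"events outside run bounds for trials {sorted(out_of_run['trial'].unique())}"
        )

    imagery_ok = {
        int(r.trial): (int(r.vividness) != 4) and bool(r.valid)
        for r in events[events["period"] == "imagery"].itertuples()
    }
    patterns = []
    for r in events.itertuples():
        run_i = int(r.run)
        window = hdr_window(
            float(r.onset), float(r.onset) + float(r.duration),
            tr_seconds, lag_trs, run_len[run_i],
        )
        vector = (
            extract_trial_pattern(runs[run_i - 1], brain_mask, window)
            if window is not None else None
        )
        patterns.append(
            TrialPattern(
                trial_index=int(r.trial),
                period=str(r.period),
                label=str(r.context),
                run_index=run_i,
                item_id=str(r.item_id) if "item_id" in events.columns else None,
                vector=vector,
                valid=imagery_ok.get(int(r.trial), True) and vector is not None,
            )
        )
    return PatternSet(patterns=patterns, voxel_index=np.flatnonzero(brain_mask.ravel()))
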