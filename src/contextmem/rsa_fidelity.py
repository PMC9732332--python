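"""Context templates and per-trial reinstatement fidelity.

Within the selected feature mask, valid imagery patterns are averaged per
context into a participant-specific *reinstatement template*.  Each
covert-recall (language) pattern is then Pearson-correlated with the template
of the probed word's learning context; the r values are Fisher-transformed to
z, and a within-participant mean split labels each trial a high- or
low-fidelity reinstatement trial (ties go to low).  Fidelity classes are then
crossed with congruency and test time to tabulate recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContextTemplate",
    "build_context_templates",
    "fidelity_score",
    "split_by_mean",
    "score_fidelity",
    "recall_by_fidelity",
]

#: |r| is clamped here before atanh; noiseless synthetic data can reach r = 1,
#: where the Fisher transform is undefined.
R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class ContextTemplate:
    context: str
    vector: np.ndarray  # over feature-mask voxels
    n_trials_averaged: int


def build_context_templates(
    imagery_patterns: np.ndarray,
    context_labels,
    feature_cols: np.ndarray,
) -> dict[str, ContextTemplate]:
    """Per-context mean of the valid imagery patterns, restricted to the mask.

    ``feature_cols`` are column indices (into the in-mask voxel ordering) of
    the selected feature voxels.  Every represented context must have at least
    one valid trial.
    """
    X = np.asarray(imagery_patterns, dtype=np.float64)[:, feature_cols]
    labels = np.asarray(context_labels)
    templates = {}
    for ctx in ("A", "B"):
        rows = np.flatnonzero(labels == ctx)
        if rows.size == 0:
            raise ValueError(f"no template: context {ctx} has no valid imagery trials")
        templates[ctx] = ContextTemplate(
            context=ctx, vector=X[rows].mean(axis=0), n_trials_averaged=int(rows.size)
        )
    return templates


def fidelity_score(language_pattern: np.ndarray, template: ContextTemplate) -> tuple[float, float]:
    """Pearson r between a recall pattern and its learning-context template,
    plus the Fisher z = atanh(r) after clamping."""
    x = np.asarray(language_pattern, dtype=np.float64)
    t = np.asarray(template.vector, dtype=np.float64)
    if x.shape != t.shape or x.size < 3:
        raise ValueError("pattern and template must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(t) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, t)[0, 1])
    z = float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))
    return r, z


def split_by_mean(z_values) -> np.ndarray:
    """'high' where z exceeds the mean, 'low' otherwise (ties to low)."""
    z = np.asarray(z_values, dtype=np.float64)
    if z.size < 2:
        raise ValueError("need at least 2 trials for a mean split")
    return np.where(z > z.mean(), "high", "low")


def score_fidelity(
    language_patterns: np.ndarray,
    language_meta: pd.DataFrame,
    templates: dict[str, ContextTemplate],
    feature_cols: np.ndarray,
    trials: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fidelity records for every valid recall trial.

    ``language_meta`` aligns rows of ``language_patterns`` with trial index,
    learning-context label and item id.  ``trials`` (optional) contributes
    ``congruency`` and recall scores by trial index.  The high/low class is a
    mean split over this participant's z values only.
    """
    X = np.asarray(language_patterns, dtype=np.float64)[:, feature_cols]
    records = []
    for row, meta in zip(X, language_meta.itertuples()):
        r, z = fidelity_score(row, templates[str(meta.label)])
        records.append(
            {"trial": int(meta.trial), "item_id": meta.item_id,
             "learning_context": str(meta.label), "r": r, "z": z}
        )
    out = pd.DataFrame(records)
    out["fidelity_class"] = split_by_mean(out["z"].to_numpy())
    if trials is not None:
        cols = [c for c in ("trial", "congruency", "recall_T4", "recall_T5") if c in trials.columns]
        out = out.merge(trials[cols], on="trial", how="left")
    return out


def recall_by_fidelity(records: pd.DataFrame) -> pd.DataFrame:
    """Participant-level mean recall per fidelity x time x congruency cell.

    Returns one row per cell with ``mean``, ``n`` and a ``missing`` flag for
    cells with no trials (never imputed).
    """
    if records.empty:
        raise ValueError("no fidelity records")
    long = records.melt(
        id_vars=["fidelity_class", "congruency"],
        value_vars=[c for c in ("recall_T4", "recall_T5") if c in records.columns],
        var_name="time", value_name="recall",
    )
    long["time"] = long["time"].str.replace("recall_", "", regex=False)
    rows = []
    for fid in ("high", "low"):
        for time in sorted(long["time"].unique()):
            for cong in ("congruent", "incongruent"):
                cell = long[
                    (long["fidelity_class"] == fid)
                    & (long["time"] == time)
                    & (long["congruency"] == cong)
                ]["recall"].dropna()
                rows.append(
                    {"fidelity_class": fid, "time": time, "congruency": cong,
                     "mean": float(cell.mean()) if len(cell) else np.nan,
                     "n": int(len(cell)), "missing": len(cell) == 0}
                )
    return pd.DataFrame(rows)
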