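"""Phoneme-level recall scoring and the forgetting/retention/intrusion calculus.

A verbal response is scored as the fraction of correct phonemes; two scorers
are reconciled by averaging.  Retention over a delay is measured inversely via
an item-wise *forgetting index* (late score minus early score, for words with a
non-zero early score) and summarised as a *retention score* of
``1 + mean(index)``: 1 means perfect retention of everything previously known,
0.5 means half the information survived, 0 means none did.  Intrusions from the
other language are counted from ordinal severity codes, taking the maximum code
when scorers disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "TIME_OF_ROUND",
    "score_word",
    "reconcile_recall",
    "apply_drop_rule",
    "forgetting_index",
    "retention_score",
    "intrusion_summary",
    "reconcile_word_scores",
    "participant_summary",
]

#: Sentinel returned by :func:`forgetting_index` for words with a zero early
#: score, which the retention calculus must skip.
EXCLUDED = "excluded"

#: Retrieval-practice rounds 2-4 are the recall measurements T1-T3.
TIME_OF_ROUND = {2: "T1", 3: "T2", 4: "T3"}

_TIME_ORDER = ("T1", "T2", "T3", "T4", "T5")


def score_word(n_correct: int, n_total: int) -> float:
    """Fraction of correct phonemes in a single scorer's judgement."""
    if n_total == 0:
        raise ValueError("empty word")
    if not 0 <= n_correct <= n_total:
        raise ValueError(f"need 0 <= n_correct <= n_total, got {n_correct}/{n_total}")
    return n_correct / n_total


def reconcile_recall(score_a: float, score_b: float) -> float:
    """Final recall score for a word: the mean of the two scorers' fractions."""
    for s in (score_a, score_b):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"scores must lie in [0, 1], got {s}")
    return (score_a + score_b) / 2.0


def apply_drop_rule(attempt_log: pd.DataFrame) -> pd.DataFrame:
    """Per-word eligibility at T1-T5 from the retrieval-practice attempt log.

    ``attempt_log`` has columns ``item_id``, ``round`` (2-4) and ``attempted``.
    A word whose recall attempt was skipped at round *k* received feedback
    without a retrieval attempt, so it is dropped from every time point after
    that round's measurement (a Round 3 skip leaves T1-T2 eligible and drops
    T3, T4 and T5); eligibility never recovers.  Missing rounds are treated
    as attempted.
    """
    required = {"item_id", "round", "attempted"}
    if not required.issubset(attempt_log.columns):
        raise ValueError(f"attempt log needs columns {sorted(required)}")
    bad = set(attempt_log["round"]) - set(TIME_OF_ROUND)
    if bad:
        raise ValueError(f"rounds must be in {sorted(TIME_OF_ROUND)}, got {sorted(bad)}")
    rows = []
    for item_id, g in attempt_log.groupby("item_id", sort=True):
        skipped = g.loc[~g["attempted"].astype(bool), "round"]
        first_drop = (
            _TIME_ORDER.index(TIME_OF_ROUND[int(skipped.min())]) + 1
            if len(skipped) else len(_TIME_ORDER)
        )
        for i, t in enumerate(_TIME_ORDER):
            rows.append({"item_id": item_id, "time": t, "eligible": i < first_drop})
    return pd.DataFrame(rows)


def forgetting_index(early_score: float, late_score: float):
    """Item-wise forgetting between two tests: ``late - early``.

    Words with a zero early score never held the information being retained
    and return the :data:`EXCLUDED` sentinel instead of a number.
    """
    for s in (early_score, late_score):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"scores must lie in [0, 1], got {s}")
    if early_score == 0.0:
        return EXCLUDED
    return late_score - early_score


def retention_score(indices) -> float:
    """Participant-level retention: ``1 + mean(forgetting indices)``.

    All-zero indices give 1 (perfect retention); a mean index of -0.5 gives
    0.5 (half the information survived the delay).
    """
    vals = [v for v in indices if v is not EXCLUDED]
    if len(vals) == 0:
        raise ValueError("no eligible words")
    return 1.0 + float(np.mean(vals))


def intrusion_summary(records: pd.DataFrame) -> pd.Series:
    """Per-participant intrusion counts under the max-code reconciliation rule.

    ``records`` has columns ``participant``, ``item_id``, ``scorer``, ``code``
    with ordinal severity codes 0-3 (0 = no intrusion).  An item counts as an
    intrusion when the maximum code across scorers is positive.
    """
    codes = records["code"].to_numpy()
    if codes.size and (codes.min() < 0 or codes.max() > 3):
        raise ValueError("intrusion codes must lie in 0-3")
    final = records.groupby(["participant", "item_id"])["code"].max()
    counts = (final > 0).groupby("participant").sum()
    return counts.astype(int)


# ---------------------------------------------------------------------------
# table-level pipeline


def reconcile_word_scores(word_scores: pd.DataFrame) -> pd.DataFrame:
    """Reconcile the two scorers of every (participant, item, time) cell.

    Input columns: ``participant, item_id, time, scorer, n_correct, n_total``.
    Output: one row per cell with the reconciled ``score``.
    """
    ws = word_scores.copy()
    ws["score"] = ws["n_correct"] / ws["n_total"].replace(0, np.nan)
    if ws["score"].isna().any():
        raise ValueError("empty word")
    out = (
        ws.groupby(["participant", "item_id", "time"], sort=True)["score"]
        .mean()
        .reset_index()
    )
    return out


def participant_summary(
    word_scores: pd.DataFrame,
    intrusions: pd.DataFrame | None = None,
    eligibility: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-participant T1-T5 mean recall plus overnight and one-week retention.

    Overnight retention compares T2 -> T3; one-week retention compares
    T4 -> T5.  Words ineligible at a time point (drop rule) contribute to
    neither the mean recall nor the retention calculus there; words with a
    zero early score are excluded from the forgetting indices.
    """
    scores = reconcile_word_scores(word_scores)
    if eligibility is not None:
        scores = scores.merge(eligibility, on=["item_id", "time"], how="left")
        scores["eligible"] = scores["eligible"].astype("boolean").fillna(True).astype(bool)
        scores = scores[scores["eligible"]]

    rows = []
    for pid, g in scores.groupby("participant", sort=True):
        wide = g.pivot_table(index="item_id", columns="time", values="score")
        row: dict = {"participant": pid}
        for t in _TIME_ORDER:
            row[f"recall_{t}"] = float(wide[t].mean()) if t in wide else np.nan
        for name, (early, late) in {
            "overnight_retention": ("T2", "T3"),
            "one_week_retention": ("T4", "T5"),
        }.items():
            if early in wide and late in wide:
                pair = wide[[early, late]].dropna()
                idx = [
                    forgetting_index(e, l)
                    for e, l in zip(pair[early], pair[late])
                ]
                vals = [v for v in idx if v is not EXCLUDED]
                row[name] = retention_score(vals) if vals else np.nan
                row[f"n_eligible_{name}"] = len(vals)
            else:
                row[name] = np.nan
                row[f"n_eligible_{name}"] = 0
        rows.append(row)
    out = pd.DataFrame(rows)

    if intrusions is not None:
        counts = intrusion_summary(intrusions).rename("intrusion_count")
        out = out.merge(counts, left_on="participant", right_index=True, how="left")
        out["intrusion_count"] = out["intrusion_count"].fillna(0).astype(int)
    return out
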