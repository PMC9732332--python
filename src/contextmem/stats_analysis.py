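"""Presence mean split and the factorial ANOVA layer.

Between-subject factors (context group, high/low presence) are analysed with a
Type III two-way ANOVA; the repeated-measures designs (time x congruency x
fidelity, optionally crossed with between factors) are analysed as univariate
mixed ANOVAs.  Because every factor here has two levels, each within-subject
effect reduces exactly to a per-subject contrast score, and its F test (error
term: effect x subject interaction) is the Type III test of that contrast's
intercept in a between-subjects regression — the same univariate F a
commercial repeated-measures package reports.  Effect sizes are partial eta
squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "AnovaResult",
    "PresenceSplit",
    "presence_split",
    "between_anova_2x2",
    "rm_anova_factorial",
    "summarize_cells",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss: float = 0.0
    ss_error: float = 0.0
    cell_means: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PresenceSplit:
    threshold: float  # sample mean of the presence scores
    assignment: dict  # participant -> "high" | "low"


def presence_split(scores: pd.Series) -> PresenceSplit:
    """Mean split of presence scores; scores at the threshold go to low."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 participants for a mean split")
    threshold = float(s.mean())
    return PresenceSplit(
        threshold=threshold,
        assignment={k: ("high" if v > threshold else "low") for k, v in s.items()},
    )


def _result_from_row(effect, ss, df_num, ss_err, df_den) -> AnovaResult:
    from scipy.stats import f as f_dist

    if not np.isfinite(ss):
        ss = 0.0  # degenerate fit: statsmodels reports NaN SS for a zero contrast
    ms, ms_err = ss / df_num, ss_err / df_den
    if ms_err > 1e-12 * max(ms, 1.0):
        F = float(ms / ms_err)
    else:
        F = 0.0 if ms <= 1e-12 else float("inf")  # no error variance
    p = float(f_dist.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    return AnovaResult(
        effect=effect, F=F, df_num=int(df_num), df_den=int(df_den), p=p,
        partial_eta_sq=float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
        ss=float(ss), ss_error=float(ss_err),
    )


def _type3_anova(df: pd.DataFrame, dv: str, factors: list[str]):
    """Type III ANOVA table of dv on fully crossed 2-level factors."""
    terms = " * ".join(f"C({f}, Sum)" for f in factors) if factors else "1"
    model = ols(f"{dv} ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    return model, table


def _clean_term(term: str) -> str:
    return (
        term.replace("C(", "").replace(", Sum)", "").replace(":", " x ").strip()
    )


def between_anova_2x2(
    values: pd.Series,
    group: pd.Series,
    presence: pd.Series,
) -> list[AnovaResult]:
    """Two-way between-subjects ANOVA (Type III) with simple main effects.

    Returns main effects of group and presence, their interaction, and the
    simple main effect of group within each presence level tested against the
    pooled error term.  Every one of the four cells must be populated.
    """
    df = pd.DataFrame({"y": pd.Series(values, dtype=float),
                       "group": pd.Series(group).astype(str),
                       "presence": pd.Series(presence).astype(str)}).dropna()
    cells = df.groupby(["group", "presence"])["y"]
    if cells.ngroups < 4 or (cells.count() == 0).any():
        raise ValueError("all four group x presence cells must be non-empty")

    _, table = _type3_anova(df, "y", ["group", "presence"])
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = int(table.loc["Residual", "df"])
    cell_means = {
        k: (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0, int(len(v)))
        for k, v in cells
    }
    results = []
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        res = _result_from_row(
            _clean_term(term), float(table.loc[term, "sum_sq"]),
            int(table.loc[term, "df"]), ss_err, df_err,
        )
        results.append(AnovaResult(**{**vars(res), "cell_means": cell_means}))

    # simple main effects of group within each presence level, pooled error
    for level in sorted(df["presence"].unique()):
        sub = df[df["presence"] == level]
        g = sub.groupby("group")["y"]
        means, ns = g.mean(), g.count()
        if len(means) < 2:
            continue
        diff = float(means.iloc[0] - means.iloc[1])
        ss = diff**2 / (1.0 / ns.iloc[0] + 1.0 / ns.iloc[1])
        results.append(
            _result_from_row(f"group within presence={level}", ss, 1, ss_err, df_err)
        )
    return results


def _contrast_scores(wide: pd.DataFrame, within: list[str], subset: tuple[str, ...]) -> pd.Series:
    """Per-subject contrast score for a within-effect (product of +-1 codes)."""
    signs = np.ones(wide.shape[1])
    for j, cell in enumerate(wide.columns):
        levels = cell if isinstance(cell, tuple) else (cell,)
        for f, lev in zip(within, levels):
            if f in subset and lev == sorted(wide.columns.get_level_values(f).unique())[1]:
                signs[j] = -signs[j]
    return (wide * signs).mean(axis=1)


def rm_anova_factorial(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: list[str] | None = None,
) -> list[AnovaResult]:
    """Univariate mixed factorial ANOVA on per-subject cell means.

    ``data`` is long-format with one or more observations per subject x
    within-cell (averaged first).  All factors must have exactly two levels.
    Within effects (and their interactions with between factors) are tested
    against the effect x subject error; pure between effects against the
    between-subject error.  Subjects missing any within cell are dropped with
    a warning.
    """
    between = between or []
    for f in within + between:
        if data[f].nunique() != 2:
            raise ValueError(f"factor {f!r} must have exactly two levels")

    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(f"dropped {len(wide) - len(complete)} subjects with incomplete cells")
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete subjects")
    if len(within) == 1:
        complete.columns = pd.MultiIndex.from_arrays([complete.columns], names=within)

    subj_between = (
        data.drop_duplicates(subject).set_index(subject)[between].loc[complete.index]
        if between else pd.DataFrame(index=complete.index)
    )

    results: list[AnovaResult] = []
    # pure between effects: ANOVA of per-subject means
    if between:
        bdf = subj_between.copy()
        bdf["y"] = complete.mean(axis=1)
        _, table = _type3_anova(bdf, "y", between)
        ss_err = float(table.loc["Residual", "sum_sq"])
        df_err = int(table.loc["Residual", "df"])
        for term in table.index:
            if term in ("Intercept", "Residual"):
                continue
            results.append(
                _result_from_row(_clean_term(term), float(table.loc[term, "sum_sq"]),
                                 int(table.loc[term, "df"]), ss_err, df_err)
            )

    # within effects and within x between interactions via contrast scores
    for size in range(1, len(within) + 1):
        for subset in itertools.combinations(within, size):
            cdf = subj_between.copy()
            cdf["c"] = _contrast_scores(complete, within, subset)
            _, table = _type3_anova(cdf, "c", between)
            ss_err = float(table.loc["Residual", "sum_sq"])
            df_err = int(table.loc["Residual", "df"])
            wname = " x ".join(subset)
            for term in table.index:
                if term == "Residual":
                    continue
                name = wname if term == "Intercept" else f"{wname} x {_clean_term(term)}"
                results.append(
                    _result_from_row(name, float(table.loc[term, "sum_sq"]),
                                     int(table.loc[term, "df"]), ss_err, df_err)
                )
    return results


def summarize_cells(
    data: pd.DataFrame, factors: list[str], values: list[str]
) -> pd.DataFrame:
    """Mean, sd, n of each value column per design cell; empty cells flagged."""
    if data.empty:
        raise ValueError("empty dataset")
    levels = [sorted(data[f].dropna().unique()) for f in factors]
    rows = []
    for combo in itertools.product(*levels):
        sel = np.ones(len(data), dtype=bool)
        for f, lev in zip(factors, combo):
            sel &= (data[f] == lev).to_numpy()
        cell = data[sel]
        row = dict(zip(factors, combo))
        row["n"] = int(len(cell))
        row["missing"] = len(cell) == 0
        for v in values:
            col = cell[v].dropna()
            row[f"{v}_mean"] = float(col.mean()) if len(col) else np.nan
            row[f"{v}_sd"] = float(col.std(ddof=1)) if len(col) > 1 else (0.0 if len(col) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
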