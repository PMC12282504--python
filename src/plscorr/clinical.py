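"""Group comparisons and downstream applications of the latent-variable scores.

Unequal-variance (Welch) t tests and Pearson chi-square tests for cohort
descriptives, subtype contrasts on LV scores, and the prospective partial
correlation between baseline LV scores and follow-up severity controlling
for baseline severity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudyDataset
from .decomposition import PlsDecomposition, score_correlation


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int
    p: float
    expected: np.ndarray


class PartialCorrelation(NamedTuple):
    r: float
    p: float
    n: int


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch two-sample t test from group summary statistics.

    t = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2) with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both group variances are zero")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def welch_t_from_samples(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch t test from two raw vectors (NaNs dropped)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    return welch_t(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)


def chi_square_independence(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(chi2), int(df), float(p), expected)


# ---------------------------------------------------------------------------
# Subtype comparison
# ---------------------------------------------------------------------------


@dataclass
class SubtypeComparison:
    """EDbp-vs-EDr contrasts on LV scores, one row per (lv, score_type)."""

    table: pd.DataFrame  # columns: lv, score_type, mean_EDr, mean_EDbp, t, df, p
    within_correlations: pd.DataFrame  # columns: lv, subtype, r, p, n
    n_edr: int
    n_edbp: int


def compare_subtypes(
    ds: StudyDataset,
    dec: PlsDecomposition,
    lvs: Sequence[int] = (0,),
) -> SubtypeComparison:
    """Welch t contrasts of brain and behavior scores between ED subtypes.

    The t statistic is signed EDr minus EDbp, so a higher-scoring
    binge-purge group yields a negative t. Also reports the brain-behavior
    score correlation within each subtype.
    """
    ed = ds.group == "ED"
    edr = ed & (ds.subtype == "EDr")
    edbp = ed & (ds.subtype == "EDbp")
    if edr.sum() < 3 or edbp.sum() < 3:
        raise ValueError(
            f"both subtypes need n >= 3 (EDr {int(edr.sum())}, EDbp {int(edbp.sum())})"
        )

    rows = []
    within = []
    for lv in lvs:
        for score_type, scores in (
            ("brain", dec.brain_scores[:, lv]),
            ("behavior", dec.behavior_scores[:, lv]),
        ):
            res = welch_t_from_samples(scores[edr], scores[edbp])
            rows.append(
                {
                    "lv": lv + 1,
                    "score_type": score_type,
                    "mean_EDr": float(scores[edr].mean()),
                    "mean_EDbp": float(scores[edbp].mean()),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
        for name, mask in (("EDr", edr), ("EDbp", edbp)):
            r, p = score_correlation(dec.brain_scores[mask, lv], dec.behavior_scores[mask, lv])
            within.append({"lv": lv + 1, "subtype": name, "r": r, "p": p, "n": int(mask.sum())})

    return SubtypeComparison(
        table=pd.DataFrame(rows),
        within_correlations=pd.DataFrame(within),
        n_edr=int(edr.sum()),
        n_edbp=int(edbp.sum()),
    )


# ---------------------------------------------------------------------------
# Prospective association
# ---------------------------------------------------------------------------


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> PartialCorrelation:
    """First-order partial correlation of x and y controlling for z.

    Computed by correlating the residuals of x-on-z and y-on-z regressions;
    cross-checked against the closed-form identity
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)). p is two-sided
    from a t distribution with n - 3 degrees of freedom.
    """
    x, y, z = (np.asarray(a, float) for a in (x, y, z))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete observations")

    def _resid(a: np.ndarray) -> np.ndarray:
        if np.std(z) == 0:
            return a - a.mean()
        zc = z - z.mean()
        beta = (zc @ (a - a.mean())) / (zc @ zc)
        return a - a.mean() - beta * zc

    rx, ry = _resid(x), _resid(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])

    if np.std(z) > 0:  # closed-form cross-check
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
        if denom > 1e-12:
            assert abs(r - (rxy - rxz * ryz) / denom) < 1e-8

    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r, p, n)


def prospective_association(
    ds: StudyDataset,
    dec: PlsDecomposition,
    lv: int = 0,
    score_type: str = "brain",
) -> PartialCorrelation:
    """Partial correlation of a baseline LV score with follow-up severity,
    controlling for baseline severity, over subjects with complete follow-up."""
    if score_type not in ("brain", "behavior"):
        raise ValueError("score_type must be 'brain' or 'behavior'")
    scores = dec.brain_scores[:, lv] if score_type == "brain" else dec.behavior_scores[:, lv]
    mask = ~np.isnan(ds.followup_severity) & ~np.isnan(ds.baseline_severity)
    if mask.sum() < 10:
        raise ValueError(
            f"insufficient follow-up data: {int(mask.sum())} complete subjects, need >= 10"
        )
    return partial_correlation(
        scores[mask], ds.followup_severity[mask], ds.baseline_severity[mask]
    )


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


@dataclass
class GroupStatsTable:
    """ED-vs-HC descriptive statistics, one row per requested variable."""

    table: pd.DataFrame


def group_descriptives(ds: StudyDataset, variables: Sequence[str]) -> GroupStatsTable:
    """Per-variable group means/SDs and a Welch t test of ED vs HC.

    Variables are looked up among behavior columns and the numeric metadata
    fields (``age``, ``ede_baseline``, ``ede_followup``). A variable with no
    non-missing values in one group is flagged and gets no test. A
    Benjamini-Hochberg adjusted p column is included as optional extra
    output; raw p-values are the primary report.
    """
    meta_numeric = {
        "age": ds.age,
        "ede_baseline": ds.baseline_severity,
        "ede_followup": ds.followup_severity,
    }
    ed = ds.group == "ED"
    hc = ds.group == "HC"

    rows = []
    for var in variables:
        if var in ds.behavior_names:
            values = ds.behavior[:, ds.behavior_names.index(var)]
        elif var in meta_numeric:
            values = meta_numeric[var]
        else:
            raise KeyError(f"unknown variable {var!r}")
        x = values[ed]
        y = values[hc]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        row = {
            "variable": var,
            "ed_n": int(x.size),
            "ed_mean": float(x.mean()) if x.size else np.nan,
            "ed_sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
            "hc_n": int(y.size),
            "hc_mean": float(y.mean()) if y.size else np.nan,
            "hc_sd": float(y.std(ddof=1)) if y.size > 1 else np.nan,
            "test": "",
            "statistic": np.nan,
            "df": np.nan,
            "p": np.nan,
            "note": "",
        }
        if x.size < 2 or y.size < 2:
            row["note"] = "missing in one group; no test"
        else:
            try:
                res = welch_t(
                    x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
                )
                row.update(test="welch_t", statistic=res.t, df=res.df, p=res.p)
            except ValueError as exc:
                row["note"] = str(exc)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("variable")
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "p_bh"] = _benjamini_hochberg(table.loc[tested, "p"].to_numpy())
    else:
        table["p_bh"] = np.nan
    return GroupStatsTable(table=table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
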