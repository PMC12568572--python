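"""Two-group cohort statistics: descriptives, t-tests, chi-square, ANCOVA.

The analysis layer mirrors a classic covariate-adjusted cohort comparison:
per-eye metric rows (both eyes enter as independent observations; a
subject-averaging switch exists for sensitivity analysis) are compared
between groups with an analysis of covariance adjusting for age, sex, and
axial length.  The group F test is the extra-sum-of-squares test between
the covariate-only and the full linear model; adjusted group means are the
model predictions at the grand covariate means.

Group labels are "HLC" and "LLC" by convention; any two labels work, with
the adjusted difference reported as first minus second in sorted order
unless ``groups`` is passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "AncovaResult",
    "percent_excess",
    "describe",
    "t_test",
    "chi_square",
    "ancova",
    "report_tables",
    "subject_means",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "axl_mm")


def percent_excess(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent: 100 * (a/b - 1)."""
    if b == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (a / b - 1.0)


@dataclass
class AncovaResult:
    outcome: str
    groups: tuple[str, str]
    adjusted_means: dict[str, float]
    adjusted_difference: float  # groups[0] - groups[1]
    F: float
    p: float
    coefficients: dict[str, float]
    n_per_group: dict[str, int]
    covariates: tuple[str, ...] = field(default_factory=tuple)


def _clean(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return table.dropna(subset=cols)


def describe(table: pd.DataFrame, outcome: str, by: str = "group") -> pd.DataFrame:
    """Per-group mean, sample SD (n-1), and n for one outcome column."""
    t = _clean(table, [outcome, by])
    rows = []
    for grp, sub in t.groupby(by, sort=True):
        n = len(sub)
        mean = float(sub[outcome].mean())
        sd = float(sub[outcome].std(ddof=1)) if n >= 2 else float("nan")
        rows.append({by: grp, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows)


def t_test(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    t = _clean(table, [outcome, group_col])
    groups = sorted(t[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, found {groups}")
    a = t.loc[t[group_col] == groups[0], outcome].to_numpy(float)
    b = t.loc[t[group_col] == groups[1], outcome].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if equal_var and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi_square(
    table: pd.DataFrame,
    categorical: str,
    group_col: str = "group",
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on the group x category contingency table."""
    t = _clean(table, [categorical, group_col])
    cont = pd.crosstab(t[group_col], t[categorical])
    if cont.shape[0] < 2 or cont.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    obs = cont.to_numpy(float)
    expected = obs.sum(axis=1, keepdims=True) @ obs.sum(axis=0, keepdims=True) / obs.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell count")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=yates)
    return float(chi2), float(p)


def _design(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...],
    group_col: str,
    groups: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = table[outcome].to_numpy(float)
    cols = [np.ones(len(table))]
    names = ["intercept"]
    cols.append((table[group_col] == groups[0]).to_numpy(float))
    names.append(f"group[{groups[0]}]")
    for cov in covariates:
        if cov == "sex":
            cols.append((table["sex"] == "male").to_numpy(float))
            names.append("sex[male]")
        else:
            cols.append(table[cov].to_numpy(float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, y, names


def ancova(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
) -> AncovaResult:
    """Linear-model group comparison adjusted for covariates.

    Fits ``outcome ~ group + covariates`` by least squares; the group test
    is the extra-sum-of-squares F between the covariate-only and the full
    model (equal to the squared group-coefficient t with one group degree
    of freedom).  Sex is encoded male=1/female=0.  Adjusted means evaluate
    the fit at the grand means of the covariates.
    """
    cols = [outcome, group_col] + [c for c in covariates]
    t = _clean(table, cols)
    found = sorted(t[group_col].unique())
    if groups is None:
        groups = tuple(found)  # type: ignore[assignment]
    if len(found) != 2:
        raise ValueError(f"expected 2 groups, found {found}")
    X, y, names = _design(t, outcome, covariates, group_col, groups)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending column: first column whose removal restores rank
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                raise ValueError(f"rank-deficient design: column {names[j]!r} is collinear")
        raise ValueError("rank-deficient design")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("too few rows for the requested model")

    full = sm.OLS(y, X).fit()
    X_red = np.delete(X, 1, axis=1)  # drop the group indicator
    red = sm.OLS(y, X_red).fit()
    df_num = 1
    df_den = int(full.df_resid)
    ss_extra = red.ssr - full.ssr
    F = float(ss_extra / df_num / (full.ssr / df_den))
    p = float(sps.f.sf(F, df_num, df_den))

    coefs = dict(zip(names, map(float, full.params)))
    # adjusted means at grand covariate means
    base = {"intercept": 1.0}
    for cov in covariates:
        if cov == "sex":
            base["sex[male]"] = float((t["sex"] == "male").mean())
        else:
            base[cov] = float(t[cov].mean())
    def predict(indicator: float) -> float:
        tot = 0.0
        for name, beta in coefs.items():
            if name == f"group[{groups[0]}]":
                tot += beta * indicator
            else:
                tot += beta * base.get(name, 0.0)
        return tot

    adj = {groups[0]: predict(1.0), groups[1]: predict(0.0)}
    n_per = {g: int((t[group_col] == g).sum()) for g in groups}
    return AncovaResult(
        outcome=outcome,
        groups=groups,  # type: ignore[arg-type]
        adjusted_means=adj,
        adjusted_difference=adj[groups[0]] - adj[groups[1]],
        F=F,
        p=p,
        coefficients=coefs,
        n_per_group=n_per,
        covariates=tuple(covariates),
    )


def subject_means(table: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Collapse both-eye rows to one row per subject (sensitivity analysis)."""
    keep = [c for c in ("subject_id", "group", "age", "sex", "axl_mm") if c in table.columns]
    agg = {c: "mean" for c in value_cols}
    return table.groupby(keep, as_index=False, sort=True).agg(agg)


# ----------------------------------------------------------------- reports

GLOBAL_PARAMS = ["VDf", "VT", "VD", "VBA", "VC", "AVR", "cup_area", "disc_area", "CDR"]
ANNULUS_PARAMS = ["VC", "VT", "VD"]
QUADRANT_PARAMS = ["VDf", "VC", "VT", "VD"]


def _scope_report(
    table: pd.DataFrame,
    scopes: list[str],
    params: list[str],
    covariates: tuple[str, ...],
    groups: tuple[str, str],
) -> pd.DataFrame:
    cols = ["parameter", "scope"]
    for g in groups:
        cols += [f"{g}_mean", f"{g}_sd", f"{g}_n"]
    cols.append("p")
    rows = []
    for param in params:
        for scope in scopes:
            sub = table[table["scope"] == scope] if "scope" in table.columns else table
            row: dict = {"parameter": param, "scope": scope}
            if param not in sub.columns or sub[param].dropna().empty:
                for g in groups:
                    row.update({f"{g}_mean": np.nan, f"{g}_sd": np.nan, f"{g}_n": 0})
                row["p"] = np.nan
                rows.append(row)
                continue
            desc = describe(sub, param)
            for g in groups:
                d = desc[desc["group"] == g]
                row[f"{g}_mean"] = float(d["mean"].iloc[0]) if len(d) else np.nan
                row[f"{g}_sd"] = float(d["sd"].iloc[0]) if len(d) else np.nan
                row[f"{g}_n"] = int(d["n"].iloc[0]) if len(d) else 0
            try:
                row["p"] = ancova(sub, param, covariates, groups=groups).p
            except ValueError:
                row["p"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def report_tables(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    annulus_labels: list[str] | None = None,
    quadrant_labels: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Global, annulus, and quadrant reports (group mean, SD, ANCOVA p).

    ``table`` holds one row per (eye, scope) with metric columns plus the
    covariates.  Missing scopes yield NaN cells; an empty cohort yields
    header-only frames.
    """
    from .zones import DEFAULT_ANNULI, QUADRANTS, annulus_label

    if annulus_labels is None:
        annulus_labels = [annulus_label(a, b) for a, b in DEFAULT_ANNULI]
    if quadrant_labels is None:
        quadrant_labels = list(QUADRANTS)
    if table.empty or "group" not in table.columns or table["group"].nunique() < 2:
        groups = ("HLC", "LLC")
        empty_cols = ["parameter", "scope"]
        for g in groups:
            empty_cols += [f"{g}_mean", f"{g}_sd", f"{g}_n"]
        empty_cols.append("p")
        empty = pd.DataFrame(columns=empty_cols)
        return {"global": empty.copy(), "annulus": empty.copy(), "quadrant": empty.copy()}
    groups = tuple(sorted(table["group"].unique()))  # type: ignore[assignment]
    return {
        "global": _scope_report(table, ["Global"], GLOBAL_PARAMS, covariates, groups),
        "annulus": _scope_report(table, annulus_labels, ANNULUS_PARAMS, covariates, groups),
        "quadrant": _scope_report(table, quadrant_labels, QUADRANT_PARAMS, covariates, groups),
    }
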