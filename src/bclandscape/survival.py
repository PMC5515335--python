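"""Shared survival machinery: Kaplan-Meier, log-rank, Cox PH, pooled-arm runs.

Disease-free survival (DFS) is time-to-first-event with right censoring.
Cox fits use the Efron approximation for tied event times and report the
hazard ratio with a Wald 95% confidence interval and p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

TIME_COL = "dfs_years"
EVENT_COL = "dfs_event"


class NoEventsError(ValueError):
    """Raised when a fit is requested on data without any observed events."""


@dataclass
class SurvivalFit:
    """Hazard ratio with Wald 95% CI and p-value for one contrast."""

    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    n_events: int
    reference_group: str | None = None
    term: str | None = None
    covariate_fits: dict[str, "SurvivalFit"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        low, high = self.ci95
        if not (low <= self.hazard_ratio <= high):
            raise ValueError("hazard ratio outside its own confidence interval")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _validate(data: pd.DataFrame) -> None:
    for col in (TIME_COL, EVENT_COL):
        if col not in data.columns:
            raise ValueError(f"survival data lacks column {col!r}")
    t = data[TIME_COL].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isinf(t).any() or (t < 0).any():
        raise ValueError("times must be finite and non-negative")
    if data[EVENT_COL].isna().any():
        raise ValueError("every sample needs an event indicator")


def km_curve(data: pd.DataFrame, group_col: str | None = None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one step table per group.

    Each table has columns ``time``, ``survival``, ``at_risk``; survival
    starts at 1 and drops only at event times.
    """
    _validate(data)
    groups = {"all": data} if group_col is None else {
        str(g): d for g, d in data.groupby(group_col, observed=True)
    }
    curves: dict[str, pd.DataFrame] = {}
    for name, d in groups.items():
        if len(d) == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(d[TIME_COL], event_observed=d[EVENT_COL])
        table = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        ).reset_index(drop=True)
    return curves


def logrank_test(data: pd.DataFrame, group_col: str) -> float:
    """Two-sided log-rank chi-square p-value across the groups."""
    _validate(data)
    counts = data[group_col].value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("log-rank test groups must be non-empty")
    res = multivariate_logrank_test(
        data[TIME_COL], data[group_col], data[EVENT_COL]
    )
    return float(res.p_value)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ValueError(
            "Cox partial likelihood failed to converge (possible complete "
            "separation / monotone likelihood)"
        ) from err
    return cph


def cox_fit(
    data: pd.DataFrame,
    group_col: str,
    reference: str | None = None,
    adjust_for: list[str] | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit for one grouping, optionally adjusted.

    A two-level (or categorical) ``group_col`` is dummy-coded against
    ``reference`` (default: alphabetically first level); a numeric column is
    treated as a continuous covariate and the HR is per unit.  Ties are
    handled with the Efron approximation (lifelines' default).  Adjustment
    covariates are dummy-coded the same way; their per-covariate fits ride
    along in ``covariate_fits``.
    """
    _validate(data)
    adjust_for = list(adjust_for or [])
    if int(data[EVENT_COL].sum()) == 0:
        raise NoEventsError("no observed events; Cox model is not estimable")

    cols: list[str] = []
    term: str
    df = data[[TIME_COL, EVENT_COL]].copy()
    if pd.api.types.is_numeric_dtype(data[group_col]) and data[group_col].nunique() > 2:
        df[group_col] = data[group_col].astype(float)
        term = group_col
        cols.append(group_col)
        reference = None
    else:
        levels = sorted(data[group_col].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"group column {group_col!r} has a single level")
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference {ref!r} not a level of {group_col!r}")
        for lev in levels:
            if lev == ref:
                continue
            name = f"{group_col}={lev}"
            df[name] = (data[group_col].astype(str) == lev).astype(float)
            cols.append(name)
        term = cols[0]
        reference = ref
    for cov in adjust_for:
        if pd.api.types.is_numeric_dtype(data[cov]):
            df[cov] = data[cov].astype(float)
            cols.append(cov)
        else:
            levels = sorted(data[cov].astype(str).unique())
            for lev in levels[1:]:
                name = f"{cov}={lev}"
                df[name] = (data[cov].astype(str) == lev).astype(float)
                cols.append(name)

    cph = _fit_cox(df, TIME_COL, EVENT_COL)
    summary = cph.summary

    def _one(row_name: str) -> SurvivalFit:
        row = summary.loc[row_name]
        return SurvivalFit(
            hazard_ratio=float(row["exp(coef)"]),
            ci95=(
                float(row["exp(coef) lower 95%"]),
                float(row["exp(coef) upper 95%"]),
            ),
            p_value=float(row["p"]),
            n=len(df),
            n_events=int(df[EVENT_COL].sum()),
            reference_group=reference,
            term=row_name,
        )

    fit = _one(term)
    fit.covariate_fits = {c: _one(c) for c in cols if c != term}
    return fit


def cox_score_test_p(data: pd.DataFrame, group_col: str) -> float:
    """P-value of the Cox partial-likelihood score test at beta = 0.

    For a two-group comparison with no tied event times this statistic is
    algebraically the log-rank chi-square, which makes it a useful
    cross-check against :func:`logrank_test`.
    """
    from scipy import stats

    _validate(data)
    levels = sorted(data[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError("score test implemented for the two-group case")
    x = (data[group_col].astype(str) == levels[-1]).to_numpy(dtype=float)
    t = data[TIME_COL].to_numpy(dtype=float)
    e = data[EVENT_COL].to_numpy(dtype=int)
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    u = 0.0
    info = 0.0
    for i in np.nonzero(e)[0]:
        at_risk = t >= t[i]
        xbar = x[at_risk].mean()
        u += x[i] - xbar
        info += xbar * (1.0 - xbar)
    if info == 0.0:
        return 1.0
    chi2 = u * u / info
    return float(stats.chi2.sf(chi2, df=1))


def pooled_arm_analysis(
    data: pd.DataFrame,
    subtype: pd.Series,
    contrasts: list[tuple[str, str, pd.Index | None]] | None = None,
    arm_col: str = "arm",
) -> dict[str, object]:
    """Prognostic analysis of subtype with treatment arms pooled.

    Arms are pooled (ignored) for the subtype-vs-outcome question; the
    function reports the across-subtype log-rank p, pairwise subtype
    contrasts within an optional sample restriction, and per-subtype
    treatment-interaction contrasts (experimental vs control within subtype).

    ``contrasts`` is a list of (subtype_a, subtype_b, restrict_index) pairs;
    each yields the Cox HR of a vs b (b as reference) within the restriction.
    """
    _validate(data)
    df = data.copy()
    df["_subtype"] = subtype.reindex(df.index)
    df = df[df["_subtype"].notna()]
    levels = df["_subtype"].unique()
    if len(levels) < 2:
        raise ValueError(
            f"between-subtype analysis needs >=2 subtypes, found {list(levels)}"
        )
    out: dict[str, object] = {
        "overall_logrank_p": logrank_test(df, "_subtype"),
    }
    pairwise: dict[str, SurvivalFit] = {}
    for a, b, restrict in contrasts or []:
        sub = df if restrict is None else df.loc[df.index.intersection(restrict)]
        sub = sub[sub["_subtype"].isin([a, b])]
        if sub[EVENT_COL].sum() == 0:
            pairwise[f"{a}_vs_{b}"] = None  # flagged: no events, HR omitted
            continue
        pairwise[f"{a}_vs_{b}"] = cox_fit(sub, "_subtype", reference=b)
    out["pairwise"] = pairwise

    interactions: dict[str, SurvivalFit | None] = {}
    if arm_col in df.columns:
        for s in sorted(pd.unique(df["_subtype"])):
            sub = df[df["_subtype"] == s]
            if sub[arm_col].nunique() < 2 or sub[EVENT_COL].sum() == 0:
                interactions[s] = None
                continue
            interactions[s] = cox_fit(sub, arm_col)
    out["arm_within_subtype"] = interactions
    return out
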