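"""Discovery and validation of genes associated with 5-year recurrence.

Patients are dichotomized at a 5-year horizon -- "early" (recurrence within
5 years) vs "late" (event-free beyond 5 years); patients censored before the
horizon are not classifiable and are excluded.  Per-gene two-sample t-tests
on log2 expression are filtered on fold change (> 1.5 or < 1/1.5) and BH
false-discovery rate (< 0.05); discovered genes are re-tested in an
independent cohort, with BH over the discovered set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import survival as surv

EARLY = "early"  # DFS event at <= horizon
LATE = "late"  # event-free beyond horizon


@dataclass
class DichotomizedCohort:
    groups: pd.Series  # sample -> early / late
    excluded: pd.DataFrame  # sample, reason
    horizon: float

    @property
    def n_early(self) -> int:
        return int((self.groups == EARLY).sum())

    @property
    def n_late(self) -> int:
        return int((self.groups == LATE).sum())


def dichotomize(data: pd.DataFrame, horizon: float = 5.0) -> DichotomizedCohort:
    """Split samples into early recurrence vs long-term event-free.

    early: event with time <= horizon; late: event-free with follow-up >
    horizon.  Everything else (censored at or before the horizon, or events
    after the horizon) is excluded with a reason.
    """
    t = data[surv.TIME_COL].astype(float)
    e = data[surv.EVENT_COL].astype(int)
    groups = pd.Series(index=data.index, dtype=object)
    reasons = {}
    for sample in data.index:
        if e[sample] == 1 and t[sample] <= horizon:
            groups[sample] = EARLY
        elif e[sample] == 0 and t[sample] > horizon:
            groups[sample] = LATE
        elif e[sample] == 1:
            reasons[sample] = f"event after horizon ({t[sample]:.2f}y)"
        else:
            reasons[sample] = f"censored at or before horizon ({t[sample]:.2f}y)"
    groups = groups.dropna()
    if (groups == EARLY).sum() == 0 or (groups == LATE).sum() == 0:
        raise ValueError("dichotomization produced an empty group")
    excluded = pd.DataFrame(
        {"reason": pd.Series(reasons, dtype=object)}
    )
    excluded.index.name = "sample"
    return DichotomizedCohort(groups=groups, excluded=excluded, horizon=horizon)


def gene_tests(
    expr: pd.DataFrame,
    cohort: DichotomizedCohort,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    equal_var: bool = True,
    literal_lower_cut: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-tests of late vs early on log2 expression.

    Fold change is oriented late over early, ``2**(mean_late - mean_early)``,
    so a protective gene (higher in long-term event-free patients) has fold
    change > 1.  The compound significance rule is fold change > 1.5 or
    < 1/1.5 (``literal_lower_cut`` uses the printed 0.67 instead) AND
    BH-adjusted p < ``fdr``.  Pooled-variance t by default; ``equal_var=False``
    switches to Welch.
    """
    early_idx = cohort.groups.index[cohort.groups == EARLY]
    late_idx = cohort.groups.index[cohort.groups == LATE]
    early_idx = expr.index.intersection(early_idx)
    late_idx = expr.index.intersection(late_idx)
    if len(early_idx) < 2 or len(late_idx) < 2:
        raise ValueError("need at least 2 samples per group")
    lower_cut = 0.67 if literal_lower_cut else 1.0 / fc_threshold

    A = expr.loc[late_idx].to_numpy(dtype=float)
    B = expr.loc[early_idx].to_numpy(dtype=float)
    t_stat, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    diff = A.mean(axis=0) - B.mean(axis=0)
    fc = np.power(2.0, diff)
    degenerate = (A.std(axis=0) == 0) & (B.std(axis=0) == 0)

    table = pd.DataFrame(
        {
            "mean_log2_diff": diff,
            "fold_change": fc,
            "t": t_stat,
            "p": p,
            "degenerate": degenerate,
        },
        index=expr.columns,
    )
    testable = ~table["degenerate"] & table["p"].notna()
    q = pd.Series(np.nan, index=table.index)
    if testable.any():
        q[testable] = multipletests(table.loc[testable, "p"], method="fdr_bh")[1]
    table["q"] = q
    table["direction"] = np.where(diff > 0, "higher-in-late", "higher-in-early")
    table["significant"] = (
        testable
        & ((table["fold_change"] > fc_threshold) | (table["fold_change"] < lower_cut))
        & (table["q"] < fdr)
    )
    table.index.name = "gene"
    return table


def validate(
    discovered: list[str],
    val_expr: pd.DataFrame,
    val_cohort: DichotomizedCohort,
    fdr: float = 0.05,
    discovery_table: pd.DataFrame | None = None,
    require_concordance: bool = True,
) -> pd.DataFrame:
    """Re-test the discovered genes in an independent cohort.

    BH adjustment runs over the discovered set only.  A gene validates when
    its adjusted p < ``fdr`` and (by default) its direction agrees with the
    discovery direction.  Genes absent from the validation matrix are
    flagged untestable.
    """
    if not discovered:
        raise ValueError("empty discovery set; nothing to validate")
    present = [g for g in discovered if g in val_expr.columns]
    absent = [g for g in discovered if g not in val_expr.columns]
    table = pd.DataFrame(index=pd.Index(discovered, name="gene"))
    table["untestable"] = [g in absent for g in discovered]
    if present:
        sub = gene_tests(val_expr[present], val_cohort, fdr=fdr)
        # re-run BH over the discovered set only (gene_tests already did,
        # since we restricted the matrix to the discovered genes)
        for col in ("mean_log2_diff", "fold_change", "t", "p", "q", "direction"):
            table.loc[present, col] = sub[col]
        validated = (table.loc[present, "q"] < fdr)
        if require_concordance and discovery_table is not None:
            concordant = (
                table.loc[present, "direction"]
                == discovery_table.loc[present, "direction"]
            )
            validated = validated & concordant
        table["validated"] = False
        table.loc[present, "validated"] = validated
    else:
        table["validated"] = False
    return table


def proliferation_correlation(
    expr: pd.DataFrame,
    discovered: list[str],
    proliferation_panel: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of discovered genes against a proliferation panel.

    Returns (r, q): the correlation matrix and BH-adjusted p-values over all
    pairs.  Constant genes yield NaN with a warning from numpy suppressed in
    favour of the NaN flag.
    """
    import warnings

    missing = [g for g in list(discovered) + list(proliferation_panel)
               if g not in expr.columns]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    n = len(expr)
    r = pd.DataFrame(index=discovered, columns=proliferation_panel, dtype=float)
    p = r.copy()
    for g1 in discovered:
        x = expr[g1].to_numpy(dtype=float)
        for g2 in proliferation_panel:
            y = expr[g2].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant gene in pair ({g1}, {g2}); correlation undefined")
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[g1, g2] = rr
            p.loc[g1, g2] = pp
    flat = p.to_numpy().ravel()
    ok = ~np.isnan(flat)
    qflat = np.full_like(flat, np.nan)
    if ok.any():
        qflat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    q = pd.DataFrame(
        qflat.reshape(p.shape), index=p.index, columns=p.columns
    )
    return r, q
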