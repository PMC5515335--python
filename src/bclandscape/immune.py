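"""Immune-gene stratification and per-gene survival association.

Within one IHC subgroup (HR+ or TNBC), samples are split into immune-high
and immune-low strata by Ward clustering on Manhattan distance over an
immune gene panel; the cluster with the higher panel-mean expression is
"immune-high".  Stratum and per-gene associations with DFS are Cox fits,
treatment-adjusted, with Benjamini-Hochberg control across the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from . import survival as surv

IMMUNE_HIGH = "immune-high"
IMMUNE_LOW = "immune-low"


@dataclass
class ImmuneStratification:
    strata: pd.Series  # sample -> immune-high / immune-low
    panel: list[str]
    subgroup: str | None = None


def immune_cluster(
    expr: pd.DataFrame, panel: list[str] | None = None, subgroup: str | None = None
) -> ImmuneStratification:
    """Two-way Ward/Manhattan clustering over the immune panel.

    The returned stratum names depend only on expression (higher panel mean
    = immune-high), never on arbitrary cluster ids, so the labelling is
    invariant to sample order.
    """
    panel = list(panel) if panel is not None else list(expr.columns)
    present = [g for g in panel if g in expr.columns]
    if len(present) < 2:
        raise ValueError("need at least 2 immune panel genes present")
    X = expr[present]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.allclose(X.to_numpy(), X.to_numpy()[0], atol=0.0):
        raise ValueError("all samples identical on the panel; no valid 2-cut")
    d = pdist(X.to_numpy(dtype=float), metric="cityblock")
    Z = linkage(d, method="ward")
    ids = fcluster(Z, t=2, criterion="maxclust")
    means = {c: float(X.to_numpy()[ids == c].mean()) for c in np.unique(ids)}
    high_id = max(means, key=lambda c: (means[c], -c))
    strata = pd.Series(
        np.where(ids == high_id, IMMUNE_HIGH, IMMUNE_LOW), index=expr.index
    )
    return ImmuneStratification(strata=strata, panel=present, subgroup=subgroup)


def stratum_survival(
    strat: ImmuneStratification,
    data: pd.DataFrame,
    adjust_for: list[str] | None = ("arm",),
) -> surv.SurvivalFit:
    """Cox HR of immune-high vs immune-low (reference), treatment-adjusted."""
    df = data.loc[strat.strata.index].copy()
    df["immune"] = strat.strata
    adjust = [c for c in (adjust_for or []) if c in df.columns]
    return surv.cox_fit(df, "immune", reference=IMMUNE_LOW, adjust_for=adjust)


def per_gene_survival(
    expr: pd.DataFrame,
    data: pd.DataFrame,
    panel: list[str],
    adjust_for: list[str] | None = ("arm",),
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-gene Cox association with DFS, BH-adjusted across the panel.

    Each gene enters its own model as a continuous covariate (standardized,
    so the HR is per standard deviation of log2 expression), adjusted for
    treatment arm.  Constant genes are skipped with a warning.  Returns one
    row per tested gene: hazard_ratio, ci_low, ci_high, p, q (BH),
    direction ('protective' for HR < 1, 'adverse' otherwise).
    """
    present = [g for g in panel if g in expr.columns]
    if not present:
        raise ValueError("no panel genes present in the expression matrix")
    samples = expr.index.intersection(data.index)
    if int(data.loc[samples, surv.EVENT_COL].sum()) == 0:
        raise surv.NoEventsError("no events among the samples to test")
    adjust = [c for c in (adjust_for or []) if c in data.columns]

    rows = []
    for gene in present:
        x = expr.loc[samples, gene].astype(float)
        sd = float(x.std(ddof=1))
        if sd == 0.0 or np.isnan(sd):
            warnings.warn(f"gene {gene!r} is constant; skipped")
            continue
        df = data.loc[samples, [surv.TIME_COL, surv.EVENT_COL] + adjust].copy()
        df[gene] = (x - x.mean()) / sd if standardize else x
        try:
            fit = surv.cox_fit(df, gene, adjust_for=adjust)
        except ValueError as err:
            warnings.warn(f"gene {gene!r} skipped: {err}")
            continue
        rows.append(
            (gene, fit.hazard_ratio, fit.ci95[0], fit.ci95[1], fit.p_value)
        )
    table = pd.DataFrame(
        rows, columns=["gene", "hazard_ratio", "ci_low", "ci_high", "p"]
    ).set_index("gene")
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["direction"] = np.where(
            table["hazard_ratio"] < 1.0, "protective", "adverse"
        )
    return table
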