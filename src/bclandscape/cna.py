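"""Relative copy-number estimation from qPCR Ct values.

One PCR cycle corresponds to one doubling of template, so Ct is a negative
log2 readout of abundance confounded by per-sample DNA input and per-assay
efficiency.  An additive two-way model Ct(s, a) = mu + sample(s) + assay(a) +
residual removes both nuisance effects by least squares; the negated residual
is the copy-number log2 signal.  Signals are averaged over a gene's assays and
anchored so the global median copy number over all genes and samples is 2
(the diploid assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CtTable:
    """Ct values (samples x assays) plus the assay -> gene map.

    Missing wells are NaN.  Values far outside the usual instrument window
    trigger a warning, not an error, so that idealized inputs (zero offsets)
    remain usable.
    """

    ct: pd.DataFrame
    assay_map: pd.Series  # assay id -> gene id
    ct_window: tuple[float, float] = (5.0, 40.0)

    def __post_init__(self) -> None:
        missing = self.ct.columns.difference(self.assay_map.index)
        if len(missing):
            raise ValueError(f"assays without gene mapping: {list(missing)[:5]}")
        self.assay_map = self.assay_map.reindex(self.ct.columns)
        lo, hi = self.ct_window
        vals = self.ct.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and ((observed < lo).any() or (observed > hi).any()):
            warnings.warn(
                f"Ct values outside the plausible window [{lo}, {hi}]",
                stacklevel=2,
            )

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.assay_map))


@dataclass
class CopyNumberTable:
    """Relative copy numbers (samples x genes), anchored to global median 2."""

    cn: pd.DataFrame
    assay_counts: pd.Series  # gene -> number of assays averaged

    def __post_init__(self) -> None:
        vals = self.cn.to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] <= 0).any():
            raise ValueError("copy numbers must be positive")


def _check_connected(mask: np.ndarray) -> None:
    """Rank check for the missing-data pattern of the two-way fit.

    Sample and assay effects are only jointly identifiable when the bipartite
    graph of observed (sample, assay) cells is connected.  Union-find over the
    observed cells; more than one component means the fit is rank deficient.
    """
    n_s, n_a = mask.shape
    parent = list(range(n_s + n_a))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for s, a in zip(*np.nonzero(mask)):
        rs, ra = find(int(s)), find(int(n_s + a))
        if rs != ra:
            parent[rs] = ra
    roots = {find(i) for i in range(n_s + n_a)}
    if len(roots) > 1:
        groups: dict[int, list[int]] = {}
        for i in range(n_s + n_a):
            groups.setdefault(find(i), []).append(i)
        desc = [
            f"(samples {[i for i in g if i < n_s]}, assays {[i - n_s for i in g if i >= n_s]})"
            for g in groups.values()
        ]
        raise ValueError(
            "missing-data pattern makes sample/assay effects non-identifiable; "
            "disconnected blocks: " + "; ".join(desc)
        )


def anova_normalize(ct: CtTable) -> pd.DataFrame:
    """Two-way additive least-squares normalization of a Ct table.

    Fits Ct(s, a) = mu + sample_effect(s) + assay_effect(a) by least squares
    over the observed cells (sum-to-zero constraints; missing cells excluded)
    and returns the negated residual as the per-(sample, assay) copy-number
    log2 signal: lower Ct than the additive model predicts means more copies.
    """
    values = ct.ct.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    empty_samples = ct.ct.index[~mask.any(axis=1)]
    empty_assays = ct.ct.columns[~mask.any(axis=0)]
    if len(empty_samples) or len(empty_assays):
        raise ValueError(
            f"entirely missing rows/columns: samples={list(empty_samples)}, "
            f"assays={list(empty_assays)}"
        )
    _check_connected(mask)

    n_s, n_a = values.shape
    s_idx, a_idx = np.nonzero(mask)
    y = values[mask]
    # Treatment-coded design; residuals are invariant to the coding.
    X = np.zeros((y.size, 1 + (n_s - 1) + (n_a - 1)))
    X[:, 0] = 1.0
    for row, (s, a) in enumerate(zip(s_idx, a_idx)):
        if s > 0:
            X[row, s] = 1.0
        if a > 0:
            X[row, n_s - 1 + a] = 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    signal = np.full_like(values, np.nan)
    signal[mask] = -(y - fitted)
    return pd.DataFrame(signal, index=ct.ct.index, columns=ct.ct.columns)


def to_copy_number(signals: pd.DataFrame, assay_map: pd.Series) -> CopyNumberTable:
    """Average assay signals per gene and anchor the global median to 2.

    The per-gene log2 signal is the mean of that gene's assays (missing assays
    skipped); linear copy numbers are rescaled multiplicatively so the median
    over all genes and samples is exactly 2.  A sample with no observed assay
    for a gene yields a missing (NaN) entry, reported with a warning.
    """
    assay_map = assay_map.reindex(signals.columns)
    gene_log2 = signals.T.groupby(assay_map).mean().T
    assay_counts = assay_map.value_counts().reindex(gene_log2.columns)

    linear = np.power(2.0, gene_log2.to_numpy(dtype=float))
    observed = linear[~np.isnan(linear)]
    if observed.size == 0:
        raise ValueError("no finite signals to anchor")
    med = float(np.median(observed))
    cn = linear * (2.0 / med)  # median is scale-equivariant: global median == 2 exactly
    table = pd.DataFrame(cn, index=signals.index, columns=gene_log2.columns)
    n_missing = int(table.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(f"{n_missing} (sample, gene) entries have no observed assay")
    return CopyNumberTable(cn=table, assay_counts=assay_counts)


def call_amplification(cn: CopyNumberTable, threshold: float = 4.0) -> pd.DataFrame:
    """Boolean amplification calls: copy number >= ``threshold``.

    The diploid anchor is 2, so the default of 4 is a two-fold gain.  Missing
    copy-number entries are called not-amplified.
    """
    if threshold <= 0:
        raise ValueError("amplification threshold must be positive")
    return cn.cn >= threshold
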