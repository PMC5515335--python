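"""Sample-level QC and housekeeping normalization for probe-count panels.

Digital counting panels (NanoString-style) carry three probe classes:
endogenous genes, housekeeping genes assumed invariant across tumors, and
negative-control probes measuring non-specific background.  A sample is kept
when a sufficient fraction of endogenous probes rises above what the negative
controls could plausibly produce; kept samples are then put on a common scale
by anchoring each sample's housekeeping level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PROBE_ENDOGENOUS = "endogenous"
PROBE_HOUSEKEEPING = "housekeeping"
PROBE_NEGATIVE = "negative"
PROBE_CLASSES = (PROBE_ENDOGENOUS, PROBE_HOUSEKEEPING, PROBE_NEGATIVE)


@dataclass
class CountMatrix:
    """Raw counts (samples x probes) with a per-probe class annotation.

    Parameters
    ----------
    counts
        Non-negative integer counts, rows are samples, columns are probes.
    probe_class
        Maps every probe id to one of ``endogenous`` / ``housekeeping`` /
        ``negative``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate probe ids in count matrix")
        missing = self.counts.columns.difference(self.probe_class.index)
        if len(missing):
            raise ValueError(f"probes without class annotation: {list(missing)[:5]}")
        self.probe_class = self.probe_class.reindex(self.counts.columns)
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")

    def probes_of(self, cls: str) -> pd.Index:
        return self.counts.columns[self.probe_class == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.counts[self.probes_of(PROBE_ENDOGENOUS)]

    @property
    def housekeeping(self) -> pd.DataFrame:
        return self.counts[self.probes_of(PROBE_HOUSEKEEPING)]

    @property
    def negative(self) -> pd.DataFrame:
        return self.counts[self.probes_of(PROBE_NEGATIVE)]


@dataclass
class QCResult:
    """Per-sample detection QC: threshold, detection rate and pass flag."""

    table: pd.DataFrame  # columns: detection_rate, threshold, zero_variance, passed
    min_detection: float

    @property
    def pass_fraction(self) -> float:
        return float(self.table["passed"].mean())

    @property
    def passing_samples(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


@dataclass
class ExpressionMatrix:
    """Log2 housekeeping-normalized expression of QC-passing samples.

    ``values`` holds endogenous genes only; ``anchor`` is the grand mean of
    per-sample housekeeping log2 means that every sample was shifted to.
    """

    values: pd.DataFrame  # samples x genes, log2 scale
    housekeeping_genes: list[str] = field(default_factory=list)
    method: str = "housekeeping-mean-log2"
    anchor: float = 0.0
    pseudocount: float = 1.0


def detection_threshold(
    negative_counts,
    level: float = 0.995,
    method: str = "prediction",
    k: float = 2.0,
) -> float:
    """Upper limit a background (negative-control) count should not exceed.

    The default is a normal-theory upper *prediction* bound on a single new
    count: ``mean + t((1+level)/2, n-1) * sd * sqrt(1 + 1/n)``.  This captures
    the question actually asked of the controls -- could this endogenous count
    have been produced by background?  A confidence bound on the control mean
    (``method="ci_mean"``) and a plain ``mean + k*sd`` rule are available for
    sensitivity analysis.

    Controls with zero variance collapse every variant to the control mean.
    """
    x = np.asarray(negative_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 negative-control counts")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return mean
    if method == "prediction":
        q = stats.t.ppf((1.0 + level) / 2.0, df=n - 1)
        return mean + q * sd * np.sqrt(1.0 + 1.0 / n)
    if method == "ci_mean":
        q = stats.t.ppf((1.0 + level) / 2.0, df=n - 1)
        return mean + q * sd / np.sqrt(n)
    if method == "mean_sd":
        return mean + k * sd
    raise ValueError(f"unknown threshold method: {method!r}")


def detection_rate(sample_counts, threshold: float) -> float:
    """Fraction of endogenous genes counted strictly above ``threshold``."""
    x = np.asarray(sample_counts, dtype=float)
    if x.size == 0:
        raise ValueError("no endogenous genes to assess")
    return float((x > threshold).mean())


def run_qc(
    counts: CountMatrix,
    min_detection: float = 0.75,
    level: float = 0.995,
    method: str = "prediction",
    per_sample: bool = True,
) -> QCResult:
    """Compute per-sample detection rates and the >= ``min_detection`` gate.

    ``per_sample=False`` pools all negative-control counts into one global
    threshold instead of one threshold per sample.
    """
    neg = counts.negative.to_numpy(dtype=float)
    if neg.shape[1] < 2:
        raise ValueError("need at least 2 negative-control probes")
    endo = counts.endogenous.to_numpy(dtype=float)
    if endo.shape[1] == 0:
        raise ValueError("no endogenous probes")

    rows = []
    global_thr = detection_threshold(neg.ravel(), level=level, method=method)
    for i, sample in enumerate(counts.counts.index):
        if per_sample:
            thr = detection_threshold(neg[i], level=level, method=method)
            zero_var = neg[i].std(ddof=1) == 0.0
        else:
            thr = global_thr
            zero_var = neg.ravel().std(ddof=1) == 0.0
        rate = detection_rate(endo[i], thr)
        rows.append((sample, rate, thr, zero_var, rate >= min_detection))
    table = pd.DataFrame(
        rows, columns=["sample", "detection_rate", "threshold", "zero_variance", "passed"]
    ).set_index("sample")
    return QCResult(table=table, min_detection=min_detection)


def normalize(
    counts: CountMatrix,
    qc: QCResult | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Log2-transform and normalize against housekeeping genes.

    Each sample's log2 counts are shifted so that its mean housekeeping log2
    value equals the cohort anchor (the grand mean of those per-sample means).
    Subtracting the per-sample housekeeping mean is equivalent to dividing raw
    counts by the geometric mean of the housekeeping genes.  Housekeeping and
    negative-control probes are dropped from the output.
    """
    hk = counts.probes_of(PROBE_HOUSEKEEPING)
    if len(hk) == 0:
        raise ValueError("no housekeeping probes; cannot normalize")
    keep = qc.passing_samples if qc is not None else counts.counts.index
    if len(keep) == 0:
        raise ValueError("no samples passed QC")

    log2_all = np.log2(counts.counts.loc[keep].astype(float) + pseudocount)
    hk_mean = log2_all[hk].mean(axis=1)
    anchor = float(hk_mean.mean())
    endo = counts.probes_of(PROBE_ENDOGENOUS)
    values = log2_all[endo].sub(hk_mean, axis=0) + anchor
    if values.isna().any().any():  # pragma: no cover - guarded by CountMatrix
        warnings.warn("NaN values produced during normalization")
    return ExpressionMatrix(
        values=values,
        housekeeping_genes=list(hk),
        anchor=anchor,
        pseudocount=pseudocount,
    )
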