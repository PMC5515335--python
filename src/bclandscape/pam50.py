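"""Intrinsic breast-cancer subtype assignment (PAM50-style).

Training labels come from a consensus of two independent routes -- nearest
centroid by rank correlation, and unsupervised hierarchical clustering -- and
only samples on which the routes agree are used to train a random-forest
classifier.  Predictions below a vote-fraction gate (default 0.4) are flagged
non-confident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

INTRINSIC_SUBTYPES = ("Basal", "Her2E", "LumA", "LumB")  # fixed tie-break order
UNASSIGNED = "unassigned"


@dataclass
class CentroidSet:
    """Per-subtype mean expression profiles over the classifier genes."""

    centroids: pd.DataFrame  # genes x subtypes

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise ValueError("need at least 2 subtype centroids")
        if self.centroids.isna().any().any():
            raise ValueError("centroids must cover every listed gene")

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)


@dataclass
class SubtypeClassifier:
    """Fitted random forest plus the gene order and OOB error it was built with."""

    model: RandomForestClassifier
    genes: list[str]
    classes: list[str]
    oob_error: float


def _corr_with_centroids(
    expr: pd.DataFrame, centroids: CentroidSet, metric: str
) -> pd.DataFrame:
    genes = expr.columns.intersection(centroids.genes)
    if len(genes) < max(2, int(np.ceil(0.5 * len(centroids.genes)))):
        raise ValueError(
            f"only {len(genes)} of {len(centroids.genes)} centroid genes present; "
            "need at least half and no fewer than 2"
        )
    X = expr[genes].to_numpy(dtype=float)
    X = X - np.median(X, axis=0)  # per-gene median centering across samples
    C = centroids.centroids.loc[genes].to_numpy(dtype=float)
    if metric == "spearman":
        X = rankdata(X, axis=1)
        C = rankdata(C, axis=0)
    elif metric != "pearson":
        raise ValueError(f"unknown metric: {metric!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    num = Xc @ Cc
    den = np.sqrt((Xc**2).sum(axis=1))[:, None] * np.sqrt((Cc**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / den
    return pd.DataFrame(corr, index=expr.index, columns=centroids.subtypes)


def nearest_centroid_call(
    expr: pd.DataFrame,
    centroids: CentroidSet,
    metric: str = "spearman",
) -> pd.DataFrame:
    """Label each sample by its most-correlated subtype centroid.

    Genes are median-centered across samples before the (default Spearman)
    correlation, which removes platform-level per-gene shifts.  Ties are
    broken by the fixed alphabetical subtype order and flagged.

    Returns a frame with columns ``label``, ``correlation``, ``tie``.
    """
    corr = _corr_with_centroids(expr, centroids, metric)
    order = sorted(corr.columns)
    corr = corr[order]
    vals = corr.to_numpy()
    best = np.argmax(vals, axis=1)
    best_val = vals[np.arange(len(vals)), best]
    tie = (np.isclose(vals, best_val[:, None])).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "label": [order[j] for j in best],
            "correlation": best_val,
            "tie": tie,
        },
        index=expr.index,
    )


def consensus_labels(
    expr: pd.DataFrame,
    centroids: CentroidSet,
    k: int | None = None,
    metric: str = "spearman",
) -> pd.Series:
    """Consensus of nearest-centroid calls and unsupervised clustering.

    Samples are clustered (Pearson correlation distance, Ward linkage) and the
    tree cut into ``k`` clusters; each cluster is named by the majority
    nearest-centroid call of its members.  A sample keeps a label only when
    its own nearest-centroid call agrees with its cluster's name; everyone
    else is ``unassigned``.  This is the platform-bias guard used to build a
    clean training set.
    """
    if k is None:
        k = len(centroids.subtypes)
    nc = nearest_centroid_call(expr, centroids, metric=metric)

    genes = expr.columns.intersection(centroids.genes)
    X = expr[genes]
    d = pdist(X.to_numpy(dtype=float), metric="correlation")
    Z = linkage(d, method="ward")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(clusters)) < k:
        raise ValueError(f"tree cut produced fewer than k={k} non-empty clusters")

    labels = pd.Series(UNASSIGNED, index=expr.index, dtype=object)
    for c in np.unique(clusters):
        members = expr.index[clusters == c]
        counts = nc.loc[members, "label"].value_counts()
        top = counts.max()
        cluster_name = sorted(counts.index[counts == top])[0]
        agree = members[nc.loc[members, "label"] == cluster_name]
        labels.loc[agree] = cluster_name
    return labels


def train_classifier(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
) -> SubtypeClassifier:
    """Fit a seeded random forest on consensus-labelled samples.

    Uses 1000 trees with sqrt(p) features per split and reports the
    out-of-bag misclassification rate.  Labelled means not ``unassigned``.
    """
    keep = labels.index[labels != UNASSIGNED]
    y = labels.loc[keep]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    per_class = y.value_counts()
    if (per_class < 5).any():
        small = per_class.index[per_class < 5].tolist()
        raise ValueError(f"classes with fewer than 5 samples: {small}")
    X = expr.loc[keep]
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(dtype=float), y.to_numpy())
    return SubtypeClassifier(
        model=model,
        genes=list(expr.columns),
        classes=list(model.classes_),
        oob_error=1.0 - float(model.oob_score_),
    )


def predict(
    classifier: SubtypeClassifier,
    expr: pd.DataFrame,
    min_probability: float = 0.4,
) -> pd.DataFrame:
    """Predict subtypes with the forest's vote fraction as the probability.

    ``confident`` is a strict ``probability > min_probability`` gate.
    Returns a frame with columns ``label``, ``probability``, ``confident``.
    """
    missing = [g for g in classifier.genes if g not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix lacks classifier genes: {missing[:5]}")
    X = expr[classifier.genes].to_numpy(dtype=float)
    proba = classifier.model.predict_proba(X)
    best = np.argmax(proba, axis=1)  # classes_ is sorted, so argmax tie-breaks alphabetically
    prob = proba[np.arange(len(best)), best]
    return pd.DataFrame(
        {
            "label": [classifier.classes[j] for j in best],
            "probability": prob,
            "confident": prob > min_probability,
        },
        index=expr.index,
    )
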