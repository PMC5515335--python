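"""TNBC molecular subtyping: Ward clustering plus ssGSEA cluster labelling.

Triple-negative tumors (ER-/PR-/HER2-) are clustered on a transcriptional
signature (Pearson correlation distance, Ward linkage, six clusters by
default) and each cluster is labelled with the Lehmann subtype -- BL1, BL2,
IM, LAR, M, MSL -- whose gene set is most enriched in the cluster's mean
expression profile, scored by a single-sample GSEA running sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

TNBC_SUBTYPES = ("BL1", "BL2", "IM", "LAR", "M", "MSL")  # fixed tie-break order


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with a stable iteration order."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.sets)) != len(self.sets):  # dict keys are unique anyway
            raise ValueError("duplicate gene-set names")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class ClusterAssignment:
    """Sample -> cluster ids plus (once labelled) cluster -> subtype names."""

    clusters: pd.Series  # sample -> int cluster id, 1..k
    labels: dict[int, str] = field(default_factory=dict)
    scores: pd.DataFrame | None = None  # clusters x gene sets enrichment
    ties: dict[int, bool] = field(default_factory=dict)

    @property
    def sample_subtype(self) -> pd.Series:
        """Per-sample subtype via the cluster labels (labels must be set)."""
        if not self.labels:
            raise ValueError("cluster labels have not been assigned yet")
        return self.clusters.map(self.labels)


def select_tnbc(annotation: pd.DataFrame) -> pd.Index:
    """Samples negative for ER, PR and HER2.

    Expects ``er`` / ``pr`` / ``her2`` columns coded ``"pos"``/``"neg"``.
    Samples with missing receptor status are excluded with a logged warning.
    """
    for col in ("er", "pr", "her2"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks receptor column {col!r}")
    status = annotation[["er", "pr", "her2"]]
    incomplete = status.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "excluding %d samples with missing receptor status", int(incomplete.sum())
        )
    triple_neg = (status == "neg").all(axis=1) & ~incomplete
    return annotation.index[triple_neg]


def cluster_tnbc(expr: pd.DataFrame, k: int = 6) -> ClusterAssignment:
    """Hierarchical clustering with Pearson correlation distance, Ward linkage.

    ``expr`` should already be restricted to the signature genes.  The tree is
    cut into ``k`` clusters by merge height; equal heights resolve by merge
    order (scipy's deterministic ordering of the agglomeration).
    """
    if expr.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {expr.shape[0]}")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 signature genes")
    X = expr.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0.0
    if constant.any():
        names = list(expr.index[constant])
        raise ValueError(
            f"constant-expression samples have undefined correlation: {names[:5]}"
        )
    d = pdist(X, metric="correlation")
    Z = linkage(d, method="ward")
    ids = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(clusters=pd.Series(ids, index=expr.index, name="cluster"))


def ssgsea_score(profile: pd.Series, gene_set, exponent: float = 0.25) -> float:
    """Single-sample GSEA enrichment of ``gene_set`` in one expression profile.

    Genes are ordered by decreasing expression (ties broken by gene name so
    the statistic is deterministic).  Walking down the list, the running sum
    gains ``rank^exponent`` -- rank N for the top gene down to 1 -- normalized
    over the in-set genes, at each set member, and loses ``1/(N - m)`` at each
    non-member.  The score is the sum of the running sum over all positions
    (the integral form), so enrichment near the top of the ranking scores
    high and enrichment at the bottom scores low.
    """
    genes_in_set = set(gene_set) & set(profile.index)
    if not genes_in_set:
        raise ValueError("gene set has no overlap with the profile")
    n = len(profile)
    m = len(genes_in_set)
    order = sorted(profile.index, key=lambda g: (-profile[g], g))
    ranks = np.arange(n, 0, -1, dtype=float)  # rank n at the top
    in_set = np.fromiter((g in genes_in_set for g in order), dtype=bool, count=n)

    weights = np.abs(ranks) ** exponent
    inc = np.where(in_set, weights, 0.0)
    denom = inc.sum()
    inc = inc / denom
    if n == m:
        dec = np.zeros(n)
    else:
        dec = np.where(~in_set, 1.0 / (n - m), 0.0)
    running = np.cumsum(inc - dec)
    return float(running.sum())


def assign_clusters(
    assignment: ClusterAssignment,
    expr: pd.DataFrame,
    genesets: GeneSetCollection,
    exponent: float = 0.25,
) -> ClusterAssignment:
    """Label each cluster with the subtype of highest mean-profile enrichment.

    For every cluster the per-gene mean expression profile is scored against
    every subtype gene set with :func:`ssgsea_score`; the cluster takes the
    argmax subtype.  Ties resolve by the collection's declared order and are
    flagged.  Several clusters may share a subtype.
    """
    cluster_ids = sorted(assignment.clusters.unique())
    scores = pd.DataFrame(index=cluster_ids, columns=genesets.names, dtype=float)
    labels: dict[int, str] = {}
    ties: dict[int, bool] = {}
    for c in cluster_ids:
        members = assignment.clusters.index[assignment.clusters == c]
        mean_profile = expr.loc[members].mean(axis=0)
        for name in genesets.names:
            scores.loc[c, name] = ssgsea_score(mean_profile, genesets[name], exponent)
        row = scores.loc[c]
        best = row.max()
        winners = [name for name in genesets.names if np.isclose(row[name], best)]
        labels[c] = winners[0]
        ties[c] = len(winners) > 1
    return ClusterAssignment(
        clusters=assignment.clusters, labels=labels, scores=scores, ties=ties
    )
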