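"""Unsupervised structure checks for small two-group expression designs.

Average-linkage (UPGMA) hierarchical clustering of samples with Pearson
correlation as the similarity measure (dissimilarity 1 - r, computed on log2
expression of a feature subset), PCA of samples on row-wise z-score
normalized values, and a phenotype-separation score that counts the minimal
number of misassigned samples under a 2-cluster cut or an optimal 1-D
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ConfigurationError
from .io import ExpressionDataset

__all__ = ["Dendrogram", "PCAResult", "cluster_samples", "pca_samples",
           "separation_score", "zscore_rows"]


@dataclass
class Dendrogram:
    """Average-linkage tree over samples.

    ``linkage`` is a scipy linkage matrix over ``leaf_ids`` (samples sorted
    by id — the deterministic tie-break); merge heights are dissimilarities
    1 - Pearson r.
    """

    linkage: np.ndarray
    leaf_ids: list[str]
    method: str = "average"
    metric: str = "1-pearson"

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k clusters."""
        labels = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(labels, index=self.leaf_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.leaf_ids)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.leaf_ids[i]
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            sa, sb = node(a), node(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            heights[i] = h
            return f"({sa}:{la:.6g},{sb}:{lb:.6g})"

        root = n + len(self.linkage) - 1
        return node(root) + ";"


@dataclass
class PCAResult:
    """Sample-space principal components of the z-scored matrix.

    ``scores``: samples x components; ``explained_variance_ratio``:
    non-increasing fractions in [0, 1]; ``loadings``: features x components,
    each column oriented so its largest-magnitude entry is positive.
    """

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def zscore_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores with the population (ddof=0) standard deviation."""
    arr = mat.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame((arr - mu) / sd, index=mat.index, columns=mat.columns)


def cluster_samples(dataset: ExpressionDataset,
                    feature_subset=None,
                    use_log2: bool = True) -> Dendrogram:
    """UPGMA tree of samples using 1 - Pearson r over a feature subset.

    Samples are ordered by id before linkage so the result does not depend on
    input order.  A sample whose profile has zero variance over the subset
    has no defined correlation and raises an error naming it.
    """
    if len(dataset.sample_meta) < 2:
        raise ConfigurationError("need at least 2 samples to cluster")
    mat = dataset.log2() if use_log2 else dataset.values
    if feature_subset is not None:
        feature_subset = list(feature_subset)
        if not feature_subset:
            raise ConfigurationError("feature subset is empty")
        mat = mat.loc[feature_subset]
    sample_ids = sorted(dataset.values.columns)
    mat = mat[sample_ids]
    arr = mat.to_numpy(float).T  # samples x features
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = sample_ids[int(np.argmax(sd == 0))]
        raise ConfigurationError(
            f"sample {bad!r} has zero variance over the subset; "
            "correlation undefined"
        )
    corr = np.corrcoef(arr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(len(sample_ids), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(Z, sample_ids)


def pca_samples(dataset: ExpressionDataset, feature_subset=None) -> PCAResult:
    """PCA of samples on row-wise z-scored log2 expression.

    Zero-variance features are dropped with a warning; at least two features
    with nonzero variance are required.
    """
    mat = dataset.log2()
    if feature_subset is not None:
        mat = mat.loc[list(feature_subset)]
    sd = mat.to_numpy(float).std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance "
                      "features before PCA")
        mat = mat.loc[sd > 0]
    if mat.shape[0] < 2:
        raise ConfigurationError(
            "need >= 2 features with nonzero variance for PCA")
    Zmat = zscore_rows(mat).to_numpy(float)  # features x samples, rows ~ N(0,1)
    # SVD of the standardized matrix; samples are the observations
    U, S, Vt = np.linalg.svd(Zmat, full_matrices=False)
    # orient each component so the largest-|loading| entry is positive
    for i in range(len(S)):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i, :] *= -1
    var = S ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    ncomp = len(S)
    comp_names = [f"PCA{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame((S[:, None] * Vt).T, index=mat.columns,
                          columns=comp_names)
    loadings = pd.DataFrame(U, index=mat.index, columns=comp_names)
    return PCAResult(scores, evr, loadings)


def separation_score(labels: pd.Series, assignment) -> int:
    """Minimal number of samples on the "wrong" side of a two-group split.

    ``labels``: group per sample ("case"/"control").  ``assignment`` is
    either a 2-cluster labeling (pd.Series of cluster ids) or a 1-D score
    vector (e.g. PCA1), in which case every threshold and both polarities are
    searched exhaustively.
    """
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ConfigurationError("separation_score needs exactly two groups")
    y = (labels == groups[1]).astype(int)

    assignment = pd.Series(assignment).reindex(labels.index)
    uniq = assignment.unique()
    if len(uniq) <= 2 and not np.issubdtype(assignment.dtype, np.floating):
        # 2-cluster partition: best of the two label<->cluster mappings
        a = (assignment == uniq[0]).astype(int)
        mis = int(min((a != y).sum(), (a == y).sum()))
        return mis
    # 1-D scores: exhaustive threshold search
    scores = assignment.astype(float).to_numpy()
    yv = y.to_numpy()
    cuts = np.concatenate([[-np.inf],
                           np.unique(scores)[:-1] + np.diff(np.unique(scores)) / 2,
                           [np.inf]])
    best = len(yv)
    for c in cuts:
        pred = (scores > c).astype(int)
        best = min(best, int((pred != yv).sum()), int((pred == yv).sum()))
    return best
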