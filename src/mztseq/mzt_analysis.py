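"""Downstream readouts of the maternal-to-zygotic transition.

From a DE table and a normalized expression matrix this module produces the
study's comparative readouts: tallies of zygotically activated (2C-enriched)
and maternally repressed (oocyte-enriched) genes and repeat families, a
sample dendrogram on correlation distance, a PCA of embryo transcriptomes,
the set of genes driving PC1, and the per-gene standardized matrix behind
the expression heat map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .annotation_io import GENE_LOCUS, REPEAT_FAMILY
from .de_core import DERecord
from .quantify import CountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DE classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonSummary:
    comparison: tuple[str, str]
    genes_up: int
    genes_down: int
    repeats_up: int
    repeats_down: int


def classify_comparison(
    de: Sequence[DERecord], cond_a: str, cond_b: str
) -> ComparisonSummary:
    """Tally significant features by direction and kind.

    "Up" means enriched in ``cond_b`` (log2fc > 0); for an oocyte-vs-2C
    comparison that is the zygotically activated set, "down" the maternally
    repressed one.
    """
    genes_up = genes_down = repeats_up = repeats_down = 0
    for r in de:
        if not (r.tested and r.significant):
            continue
        up = r.log2fc > 0
        if r.kind == GENE_LOCUS:
            genes_up += up
            genes_down += not up
        elif r.kind == REPEAT_FAMILY:
            repeats_up += up
            repeats_down += not up
    return ComparisonSummary(
        comparison=(cond_a, cond_b),
        genes_up=int(genes_up), genes_down=int(genes_down),
        repeats_up=int(repeats_up), repeats_down=int(repeats_down),
    )


# ---------------------------------------------------------------------------
# Expression transforms
# ---------------------------------------------------------------------------


def log_transform(matrix_norm: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount), features x samples."""
    if (matrix_norm.counts.values < 0).any():
        raise ValueError("negative expression values")
    return np.log2(matrix_norm.counts + pseudocount)


# ---------------------------------------------------------------------------
# Sample clustering
# ---------------------------------------------------------------------------


@dataclass
class SampleDendrogram:
    sample_ids: list[str]  # leaf order of the dendrogram
    linkage: np.ndarray
    newick: str
    cophenetic: pd.DataFrame  # samples x samples merge heights

    def cophenetic_distance(self, a: str, b: str) -> float:
        return float(self.cophenetic.loc[a, b])


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.10g}"

    body = f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)})"
    return body + ";"


def hierarchical_cluster_samples(
    expr: pd.DataFrame,
    metric: str = "correlation",
    method: str = "average",
) -> SampleDendrogram:
    """Cluster samples of a features x samples expression matrix.

    Distance defaults to 1 - Pearson correlation across features with
    average linkage.  Columns are sorted by sample id before linkage so leaf
    order (and tie-breaking among equidistant samples) is deterministic.
    Branch lengths in the exported newick are differences of merge heights.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    expr = expr[sorted(expr.columns)]
    X = expr.T.values  # samples x features
    if metric == "correlation":
        sds = X.std(axis=1)
        flat = [s for s, sd in zip(expr.columns, sds) if sd == 0]
        if flat:
            raise ValueError(f"zero-variance sample(s): {flat}; correlation distance undefined")
    d = pdist(X, metric=metric)
    Z = hierarchy.linkage(d, method=method)
    coph = squareform(hierarchy.cophenet(Z))
    labels = list(expr.columns)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return SampleDendrogram(
        sample_ids=order,
        linkage=Z,
        newick=_linkage_to_newick(Z, labels),
        cophenetic=pd.DataFrame(coph, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    sample_scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_fraction: np.ndarray


def principal_components(expr: pd.DataFrame) -> PCAResult:
    """PCA of samples on per-feature-centered (not scaled) log expression.

    Samples are observations, features variables.  Sign convention: the
    feature with the largest absolute loading on each component loads
    positively.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = expr.T.values  # samples x features; PCA centers each column (feature)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if n_comp < 2:
        raise ValueError("fewer than 2 non-degenerate dimensions")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components
    for k in range(n_comp):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PCAResult(
        sample_scores=pd.DataFrame(scores, index=expr.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=expr.index, columns=comp_names),
        variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def select_pc1_features(pca: PCAResult, k_sd: float = 2.0) -> list[str]:
    """Features whose |PC1 loading| exceeds ``k_sd`` standard deviations of
    all PC1 loadings — the deterministic stand-in for 'associated with PC1'."""
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    l1 = pca.loadings["PC1"].values
    thresh = k_sd * l1.std()
    return [f for f, v in zip(pca.loadings.index, l1) if abs(v) > thresh]


# ---------------------------------------------------------------------------
# Heat-map matrix
# ---------------------------------------------------------------------------


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame  # clustered feature rows x samples, standardized


def standardized_heatmap(expr: pd.DataFrame, features: Sequence[str]) -> HeatmapMatrix:
    """Per-gene standardized expression, rows ordered by gene clustering.

    Each selected row is centered to mean 0 and scaled to sample standard
    deviation 1 (denominator n-1), so color encodes expression relative to
    the gene's own mean and variance.  Zero-variance rows are dropped with a
    warning; rows are sorted by average-linkage clustering of the
    standardized rows.
    """
    sub = expr.loc[list(features)]
    sds = sub.std(axis=1, ddof=1)
    flat = sub.index[sds == 0].tolist()
    if flat:
        warnings.warn(f"dropping {len(flat)} zero-variance row(s)")
        sub = sub.drop(index=flat)
        sds = sds.drop(index=flat)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sds, axis=0)
    if len(z) > 2:
        Z = hierarchy.linkage(pdist(z.values, metric="euclidean"), method="average")
        z = z.iloc[hierarchy.leaves_list(Z)]
    return HeatmapMatrix(values=z)
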