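"""Distance-based comparison of cell models against the PHH/liver benchmark.

The central statistic is the distance-based similarity score (DBS).  For a
sample with Euclidean distance ``Dist_PHH`` to a PHH/liver control, over the
genes of a chosen gene set,

    DBS = (Max_PHH - Dist_PHH) / Max_PHH

where ``Max_PHH`` is the maximum distance between any retained
(sample, control) pair within the same gene-set-restricted matrix.  A DBS of
1 means indistinguishable from the benchmark; 0 marks the least similar
pair.  With several controls a sample gets one DBS per control and is
summarized by the median.

The module also provides top-variance PCA, complete-linkage hierarchical
clustering over Euclidean distances (Newick output), per-gene mean-centering
for heatmaps, and percent-of-control scaling of reported functional assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from ._errors import ValidationError
from .io import GeneSet, SampleMetadata
from .normalize import NormalizedMatrix


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances over a stated gene subset."""

    distances: pd.DataFrame  # square, symmetric, zero diagonal
    gene_set_name: str = "all_genes"
    n_genes_matched: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.distances.index)


@dataclass
class DBSResult:
    """Similarity of every sample to the PHH/liver benchmark for one gene set.

    ``pairwise`` has one row per retained (sample, control) pair with columns
    ``sample_id``, ``control_id``, ``dist_phh``, ``dbs``; ``median_dbs`` is
    the per-sample summary over controls.
    """

    gene_set_name: str
    pairwise: pd.DataFrame
    median_dbs: pd.Series
    max_phh: float


@dataclass
class PcaResult:
    """Sample coordinates and explained-variance fractions from top-variance PCA."""

    coordinates: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_fraction: np.ndarray
    n_top_genes: int
    genes_used: list[str] = field(default_factory=list)


def _restrict(matrix: NormalizedMatrix, gene_set: GeneSet | None) -> pd.DataFrame:
    df = matrix.data
    if gene_set is None:
        return df
    present = [g for g in df.index if g in gene_set.gene_ids]
    if len(present) < 2:
        raise ValidationError(
            f"gene set {gene_set.name!r}: only {len(present)} of its genes are "
            "present in the matrix (need >= 2)"
        )
    return df.loc[present]


def distance_matrix(
    matrix: NormalizedMatrix, gene_set: GeneSet | None = None
) -> DistanceMatrix:
    """Euclidean distances between samples over (a gene set's) genes."""
    df = _restrict(matrix, gene_set)
    d = squareform(pdist(df.to_numpy().T, metric="euclidean"))
    dist = pd.DataFrame(d, index=df.columns, columns=df.columns)
    return DistanceMatrix(
        distances=dist,
        gene_set_name=gene_set.name if gene_set is not None else "all_genes",
        n_genes_matched=df.shape[0],
    )


def dbs_scores(
    dist: DistanceMatrix,
    metadata: SampleMetadata,
    exclude_self: bool = True,
) -> DBSResult:
    """Distance-based similarity of every sample to each PHH/liver control.

    ``Max_PHH`` is taken over all retained (sample, control) pairs in the
    matrix, PHH-to-PHH pairs included, self-pairs excluded when
    ``exclude_self`` (the default, so the benchmark's internal spread is
    scored too).  When every distance is zero all scores are 1.
    """
    controls = [c for c in metadata.phh_controls() if c in dist.sample_ids]
    if not controls:
        raise ValidationError(
            "no PHH/Liver control samples present in the distance matrix"
        )
    rows = []
    for s in dist.sample_ids:
        for c in controls:
            if exclude_self and s == c:
                continue
            rows.append((s, c, float(dist.distances.loc[s, c])))
    pairs = pd.DataFrame(rows, columns=["sample_id", "control_id", "dist_phh"])
    max_phh = float(pairs["dist_phh"].max())
    if max_phh == 0.0:
        import warnings

        warnings.warn("all samples identical to PHH controls; every DBS set to 1")
        pairs["dbs"] = 1.0
    else:
        pairs["dbs"] = (max_phh - pairs["dist_phh"]) / max_phh
    median = pairs.groupby("sample_id", sort=False)["dbs"].median()
    median = median.reindex(dist.sample_ids).dropna()
    median.name = "median_dbs"
    return DBSResult(
        gene_set_name=dist.gene_set_name,
        pairwise=pairs,
        median_dbs=median,
        max_phh=max_phh,
    )


def pca_top_variance(matrix: NormalizedMatrix, n_top: int = 5000) -> PcaResult:
    """PCA of samples over the highest-variance genes.

    Genes are ranked by across-sample variance, the top ``n_top`` retained
    (all genes when fewer are available), gene-wise centered (no scaling to
    unit variance), and decomposed by SVD.  Components are oriented so that
    each loading vector's largest-magnitude entry is positive, making signs
    deterministic.
    """
    if n_top < 2:
        raise ValidationError("n_top must be >= 2")
    df = matrix.data
    if df.shape[1] < 2:
        raise ValidationError("PCA needs at least two samples")
    variances = df.var(axis=1, ddof=1)
    if variances.sum() == 0:
        raise ValidationError("matrix has zero total variance")
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    sub = df.loc[top]
    centered = sub.to_numpy() - sub.to_numpy().mean(axis=1, keepdims=True)
    # samples as observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u * s[None, :]
    total_var = (s**2).sum()
    var_frac = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=df.columns, columns=cols)
    return PcaResult(
        coordinates=coordinates,
        variance_fraction=var_frac,
        n_top_genes=sub.shape[0],
        genes_used=list(top),
    )


def _tree_to_newick(node: sch.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_cluster(
    matrix: NormalizedMatrix,
    gene_set: GeneSet | None = None,
    method: str = "complete",
) -> str:
    """Agglomerative clustering of samples on Euclidean distances.

    Samples are processed in lexicographic id order so ties break
    deterministically and the tree is invariant to input column order.
    Returns the dendrogram serialized in Newick format.
    """
    dist = distance_matrix(matrix, gene_set)
    if len(dist.sample_ids) < 2:
        raise ValidationError("clustering needs at least two samples")
    labels = sorted(dist.sample_ids)
    d = dist.distances.loc[labels, labels].to_numpy()
    linkage = sch.linkage(squareform(d, checks=False), method=method)
    tree = sch.to_tree(linkage)
    return _tree_to_newick(tree, labels) + ";"


def center_rows_log2fc(matrix: NormalizedMatrix) -> pd.DataFrame:
    """Subtract each gene's across-sample mean ("Log2FC RNA Expression")."""
    df = matrix.data
    centered = df.sub(df.mean(axis=1), axis=0)
    centered.attrs["label"] = "Log2FC RNA Expression"
    return centered


def percent_of_control(values, control_value: float):
    """Scale assay readouts to percent of the same-study PHH control."""
    if control_value <= 0:
        raise ValidationError("control value must be positive")
    return 100.0 * np.asarray(values, float) / float(control_value)
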