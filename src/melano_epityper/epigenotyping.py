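"""Methylation epigenotyping by unsupervised two-way hierarchical clustering.

Among genes with high- or intermediate-CpG promoters, those whose
representative-probe betas vary across tumors (sample SD > 0.15, capped at
the top 2000 by SD) are clustered together with the tumor samples
(Ward linkage on Euclidean distance, both axes). Cutting the sample
dendrogram into two clusters yields the high- and low-methylation
epigenotypes; the cluster with the greater mean beta over the selected
genes is labeled "high". Normal reference samples never enter the linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .config import ClusterParams, ValidationError

HIGH = "high"
LOW = "low"


class DegenerateMatrixError(ValidationError):
    """Clustering input admits no two distinguishable clusters."""


def select_variable_genes(
    betas: pd.DataFrame,
    sd_threshold: float = 0.15,
    top_n: int = 2000,
) -> pd.DataFrame:
    """Rank genes by cross-tumor variability of their promoter methylation.

    ``betas`` is genes x tumor samples. Sample standard deviation (n-1
    denominator) is computed per gene; genes with SD strictly above
    ``sd_threshold`` qualify, and at most ``top_n`` (by descending SD) are
    returned as a frame with an ``sd`` column. Raises when no gene
    qualifies.
    """
    if betas.shape[1] < 2:
        raise ValidationError("need at least 2 samples to compute SDs")
    sd = betas.std(axis=1, ddof=1)
    keep = sd[sd > sd_threshold].sort_values(ascending=False, kind="mergesort")
    if keep.empty:
        raise ValidationError(
            f"no gene exceeds the SD threshold of {sd_threshold}"
        )
    keep = keep.iloc[:top_n]
    return pd.DataFrame({"sd": keep})


def hierarchical_cluster(
    betas: pd.DataFrame, params: Optional[ClusterParams] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-way agglomerative clustering of a genes x samples beta matrix.

    Returns ``(sample_linkage, gene_linkage)`` in scipy linkage encoding.
    """
    params = (params or ClusterParams()).validate()
    if betas.shape[0] < 2 or betas.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 genes and 2 samples")
    sample_d = pdist(betas.to_numpy().T, metric=params.metric)
    gene_d = pdist(betas.to_numpy(), metric=params.metric)
    sample_linkage = hierarchy.linkage(sample_d, method=params.linkage)
    gene_linkage = hierarchy.linkage(gene_d, method=params.linkage)
    return sample_linkage, gene_linkage


@dataclass
class EpigenotypeResult:
    selected_genes: pd.DataFrame      # index gene, column sd (descending)
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    labels: pd.Series                 # sample -> "high" | "low"
    cluster_means: dict               # label -> mean beta over selected genes

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())


def assign_epigenotype(
    sample_linkage: np.ndarray, betas: pd.DataFrame, k: int = 2
) -> Tuple[pd.Series, dict]:
    """Cut the sample dendrogram into two clusters and name them.

    The cluster with strictly greater mean beta over the selected genes is
    "high". Raises :class:`DegenerateMatrixError` when the cut does not
    produce two distinguishable clusters (e.g. an all-equal matrix).
    """
    if k != 2:
        raise ValidationError("only a two-cluster cut is supported")
    flat = hierarchy.fcluster(sample_linkage, t=2, criterion="maxclust")
    if len(set(flat)) != 2:
        raise DegenerateMatrixError("dendrogram cut did not yield two clusters")
    samples = betas.columns
    means = {c: float(betas.loc[:, flat == c].to_numpy().mean()) for c in (1, 2)}
    if means[1] == means[2]:
        raise DegenerateMatrixError("clusters have identical mean beta")
    high_cluster = 1 if means[1] > means[2] else 2
    labels = pd.Series(
        np.where(flat == high_cluster, HIGH, LOW), index=samples, name="epigenotype"
    )
    cluster_means = {
        HIGH: means[high_cluster],
        LOW: means[1 if high_cluster == 2 else 2],
    }
    return labels, cluster_means


def epigenotype(
    tumor_betas: pd.DataFrame, params: Optional[ClusterParams] = None
) -> EpigenotypeResult:
    """Full epigenotyping of a genes x tumors beta matrix.

    ``tumor_betas`` must already be restricted to HCP/ICP representative
    genes and tumor columns.
    """
    params = (params or ClusterParams()).validate()
    selected = select_variable_genes(tumor_betas, params.sd_threshold, params.top_n)
    sub = tumor_betas.loc[selected.index]
    sample_linkage, gene_linkage = hierarchical_cluster(sub, params)
    labels, means = assign_epigenotype(sample_linkage, sub)
    return EpigenotypeResult(
        selected_genes=selected,
        sample_linkage=sample_linkage,
        gene_linkage=gene_linkage,
        labels=labels,
        cluster_means=means,
    )
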