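"""Correlated-module discovery and signature expansion.

Seed clusters are found by complete-linkage hierarchical clustering of the
most variant probes under the uncentered-correlation similarity (cosine
similarity of the row vectors, which is scale- but not location-invariant —
the convention of the classic Cluster/TreeView programs), computed on
row-standardized data. A seed cluster's centroid is the per-sample average
of its member probes' log2 values; the full signature is every probe in the
dataset whose profile has Pearson r >= 0.7 with that centroid. The top
members by centroid correlation serve as single-gene surrogate biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_R_MIN = 0.7
DEFAULT_TOP_K = 500


def rank_by_variance(values: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """Top-``k`` probes by variance across samples, descending.

    Zero-variance rows are never selected; ties break deterministically by
    probe id. If fewer than ``k`` probes have positive variance the list is
    truncated with a warning.
    """
    var = values.var(axis=1, ddof=0)
    var = var[var > 0]
    if len(var) < k:
        warnings.warn(f"only {len(var)} probes with positive variance; truncating from k={k}", stacklevel=2)
        k = len(var)
    order = sorted(var.index, key=lambda p: (-var[p], p))
    return order[:k]


def uncentered_correlation(x, y) -> float:
    """Uncentered (cosine) correlation: sum(x*y) / sqrt(sum(x^2) sum(y^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    nx, ny = np.sqrt(x @ x), np.sqrt(y @ y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector in uncentered correlation")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def hierarchical_cluster(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering with distance 1 - uncentered correlation.

    Rows are sorted by probe id before computing distances, so the merge
    tree and leaf order are deterministic functions of the input values.
    Returns the scipy linkage matrix (over the sorted rows) and the leaf
    order as probe ids. All-zero rows have undefined similarity and raise.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    ordered = values.sort_index()
    arr = ordered.to_numpy(float)
    norms = np.sqrt((arr**2).sum(axis=1))
    if (norms == 0).any():
        bad = list(ordered.index[norms == 0])[:5]
        raise ValueError(f"all-zero rows cannot be clustered: {bad}")
    dist = pdist(arr, metric="cosine")  # 1 - uncentered correlation
    dist = np.clip(dist, 0.0, None)
    link = hierarchy.linkage(dist, method="complete")
    leaves = hierarchy.leaves_list(link)
    return link, [ordered.index[i] for i in leaves]


@dataclass
class SeedCluster:
    """A flat cluster cut from the dendrogram."""

    probes: list[str]
    mean_correlation: float  # mean pairwise Pearson r among members

    def __len__(self) -> int:
        return len(self.probes)


def _mean_pairwise_pearson(arr: np.ndarray) -> float:
    if arr.shape[0] < 2:
        return 1.0
    sd = arr.std(axis=1)
    arr = arr[sd > 0]
    if arr.shape[0] < 2:
        return 0.0
    corr = np.corrcoef(arr)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def extract_seed_clusters(
    values: pd.DataFrame,
    linkage: np.ndarray,
    min_size: int = 20,
    max_clusters: int = 6,
) -> list[SeedCluster]:
    """Cut the dendrogram into at most ``max_clusters`` flat clusters.

    Clusters smaller than ``min_size`` are discarded (the cut may therefore
    return fewer clusters, or none). Each retained cluster is annotated with
    its mean within-cluster pairwise Pearson correlation, computed on the
    same rows that were clustered; clusters are ordered by size descending,
    ties by first probe id.
    """
    ordered = values.sort_index()
    labels = hierarchy.fcluster(linkage, t=max_clusters, criterion="maxclust")
    clusters: list[SeedCluster] = []
    for lab in np.unique(labels):
        probes = list(ordered.index[labels == lab])
        if len(probes) < min_size:
            continue
        arr = ordered.loc[probes].to_numpy(float)
        clusters.append(SeedCluster(probes=probes, mean_correlation=_mean_pairwise_pearson(arr)))
    clusters.sort(key=lambda c: (-len(c), c.probes[0]))
    return clusters


def signature_centroid(values_log2: pd.DataFrame, seed_probes) -> pd.Series:
    """Per-sample arithmetic mean of the seed probes' log2 values."""
    seed_probes = list(seed_probes)
    if not seed_probes:
        raise ValueError("empty seed probe list")
    missing = set(seed_probes) - set(values_log2.index)
    if missing:
        raise KeyError(f"seed probes not in matrix: {sorted(missing)[:5]}")
    return values_log2.loc[seed_probes].mean(axis=0)


@dataclass
class SignatureModel:
    """A discovered expression signature.

    ``members`` maps each member probe to its Pearson correlation with the
    seed centroid (all >= ``r_min``); ``surrogates`` are the top members by
    that correlation, usable as single-gene stand-ins for the signature.
    """

    name: str
    seed_probes: list[str]
    centroid: pd.Series
    members: pd.Series
    r_min: float = DEFAULT_R_MIN
    surrogates: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def probes(self) -> list[str]:
        return list(self.members.index)

    def gene_counts(self, probe_annotations: pd.Series) -> tuple[int, int]:
        """(number of member probes, number of unique gene symbols)."""
        symbols = probe_annotations.reindex(self.members.index).dropna()
        return len(self.members), len(set(symbols.astype(str)))


def expand_signature(
    values_log2: pd.DataFrame,
    centroid: pd.Series,
    r_min: float = DEFAULT_R_MIN,
    name: str = "signature",
    seed_probes=None,
) -> SignatureModel:
    """All probes whose profile has Pearson r >= ``r_min`` with the centroid.

    The correlation is computed across all samples on the supplied (log2)
    values; Pearson r is affine-invariant, so z-scored input gives identical
    membership. Constant probe rows are excluded (their correlation is
    undefined); a constant centroid raises.
    """
    c = centroid.reindex(values_log2.columns).to_numpy(float)
    c_sd = c.std()
    if c_sd == 0:
        raise ValueError("constant centroid: correlations undefined")
    arr = values_log2.to_numpy(float)
    arr_c = arr - arr.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt((arr_c**2).sum(axis=1)) * np.sqrt(cc @ cc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (arr_c @ cc) / denom
    r = pd.Series(r, index=values_log2.index).dropna()
    members = r[r >= r_min].sort_values(ascending=False)
    model = SignatureModel(
        name=name,
        seed_probes=list(seed_probes) if seed_probes is not None else [],
        centroid=centroid,
        members=members,
        r_min=r_min,
    )
    model.surrogates = select_surrogates(model, k=min(2, len(members)))
    return model


def select_surrogates(model: SignatureModel, k: int = 2) -> pd.Series:
    """Top-``k`` member probes by correlation with the centroid.

    Returned as probe -> r, descending; deterministic tie-break by probe id.
    """
    items = sorted(model.members.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.Series({p: r for p, r in items}, dtype=float)
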