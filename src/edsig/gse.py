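"""Parametric gene-set enrichment (PAGE-style size-adjusted z-scores).

A gene set of effective size m (genes present in the metric universe) is
scored as Z = (Sm - mu) * sqrt(m) / delta, where Sm is the mean metric over
the set and mu, delta are the mean and population SD of the whole metric
vector; the two-sided p-value comes from the standard normal. Three input
metrics are supported: the z-ratio (standardized difference of group-mean
within-sample z-scores, for within-study contrasts), the simple difference
of group mean log2 values (for external datasets), and, in the per-sample
"landscape" variant, each sample's own row-normalized expression vector —
giving a sets x samples score matrix whose group averages expose
disease-specific gene-set activity.

Probe-level matrices are collapsed to gene level by keeping, per gene
symbol, the probe with the highest mean expression; symbols match
case-insensitively (uppercased), with no alias expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

MIN_SET_SIZE = 10
P_CUTOFF = 0.01


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(dict.fromkeys(g.upper() for g in self.genes)))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance label."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    source: str = ""

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def union(self, other: "GeneSetCollection | Iterable[GeneSet]") -> "GeneSetCollection":
        merged = GeneSetCollection(sets=dict(self.sets), source=self.source)
        for gs in other:
            merged.add(gs)
        return merged


@dataclass
class MetricVector:
    """A per-gene score vector with its summary moments.

    ``kind`` records how the metric was built (zratio | difference |
    per_sample_z); ``mu``/``delta`` are the mean and population SD over the
    current universe and are recomputed on the fly, so subsetting the
    scores automatically refreshes them.
    """

    scores: pd.Series
    kind: str
    label: str = ""

    def __post_init__(self):
        arr = self.scores.to_numpy(float)
        if not np.isfinite(arr).all():
            raise ValueError("metric contains non-finite values")

    @property
    def mu(self) -> float:
        return float(self.scores.mean())

    @property
    def delta(self) -> float:
        return float(self.scores.to_numpy(float).std())  # population SD

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class EnrichmentScore:
    set_name: str
    m: int
    s_mean: float
    z: float
    p: float
    reported: bool = True


def collapse_to_genes(values: pd.DataFrame, probe_annotations: pd.Series) -> pd.DataFrame:
    """Collapse a probes x samples frame to genes x samples.

    Keeps, per (uppercased) gene symbol, the probe with the highest mean
    value; probes without a symbol are dropped. Deterministic: ties in mean
    break by probe id.
    """
    symbols = probe_annotations.reindex(values.index).dropna().astype(str).str.upper()
    sub = values.loc[symbols.index]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"gene": symbols.to_numpy(), "mean": means.to_numpy(), "probe_id": symbols.index.to_numpy()}
    )
    frame = frame.sort_values(["gene", "mean", "probe_id"], ascending=[True, False, True])
    best = frame.drop_duplicates("gene")
    out = sub.loc[best["probe_id"]]
    out.index = pd.Index(best["gene"].to_numpy(), name="gene")
    return out


def zratio_metric(
    gene_z: pd.DataFrame, samples_a: Sequence[str], samples_b: Sequence[str], label: str = ""
) -> MetricVector:
    """Z-ratio metric for a within-study contrast.

    Input rows are genes, columns within-sample z-scores. Per gene the
    difference of group means d_g = mean_z(A) - mean_z(B) is computed and
    then standardized over genes (population SD), so the metric has mean 0
    and SD 1. A degenerate all-equal difference vector yields all zeros
    with a warning.
    """
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("empty sample group")
    d = gene_z[list(samples_a)].mean(axis=1) - gene_z[list(samples_b)].mean(axis=1)
    sd = d.to_numpy().std()
    if sd == 0:
        warnings.warn("degenerate z-ratio (constant differences); returning zeros", stacklevel=2)
        scores = pd.Series(0.0, index=d.index)
    else:
        scores = (d - d.mean()) / sd
    return MetricVector(scores=scores, kind="zratio", label=label)


def difference_metric(
    gene_log2: pd.DataFrame, samples_a: Sequence[str], samples_b: Sequence[str], label: str = ""
) -> MetricVector:
    """Simple difference of group mean log2 values per gene (external data)."""
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("empty sample group")
    d = gene_log2[list(samples_a)].mean(axis=1) - gene_log2[list(samples_b)].mean(axis=1)
    return MetricVector(scores=d, kind="difference", label=label)


def page_score(metric: MetricVector, genes: Iterable[str], min_size: int = MIN_SET_SIZE, set_name: str = "") -> EnrichmentScore:
    """Size-adjusted z-score of one gene set against a metric vector."""
    delta = metric.delta
    if delta == 0:
        raise ValueError("metric SD is zero; enrichment undefined")
    universe = metric.scores
    wanted = {g.upper() for g in genes}
    hits = universe.index[universe.index.astype(str).str.upper().isin(wanted)]
    m = len(hits)
    if m < min_size:
        return EnrichmentScore(set_name=set_name, m=m, s_mean=np.nan, z=np.nan, p=np.nan, reported=False)
    s_mean = float(universe.loc[hits].mean())
    z = (s_mean - metric.mu) * np.sqrt(m) / delta
    p = 2.0 * stats.norm.sf(abs(z))
    return EnrichmentScore(set_name=set_name, m=m, s_mean=s_mean, z=float(z), p=float(p))


def score_collection(
    metric: MetricVector,
    collection: GeneSetCollection,
    min_size: int = MIN_SET_SIZE,
    p_cutoff: float = P_CUTOFF,
) -> pd.DataFrame:
    """Score every reportable set; one row per set passing the size filter.

    Rows are sorted by descending Z; the ``significant`` flag marks
    p <= ``p_cutoff``. The score sign is preserved: negative Z means the
    set's genes average below the metric mean (lower in the first group).
    """
    rows = []
    for gs in collection:
        es = page_score(metric, gs.genes, min_size=min_size, set_name=gs.name)
        if not es.reported:
            continue
        rows.append(
            {
                "set": es.set_name,
                "m": es.m,
                "s_mean": es.s_mean,
                "z": es.z,
                "p": es.p,
                "neg_log10_p": -np.log10(es.p) if es.p > 0 else np.inf,
                "significant": es.p <= p_cutoff,
            }
        )
    frame = pd.DataFrame(rows, columns=["set", "m", "s_mean", "z", "p", "neg_log10_p", "significant"])
    if len(frame):
        frame = frame.sort_values(["z", "set"], ascending=[False, True]).reset_index(drop=True)
    return frame


def _membership_matrix(collection: GeneSetCollection, universe: pd.Index, min_size: int):
    """Indicator matrix (sets x genes) over the universe; small sets dropped."""
    uni_upper = pd.Index(universe.astype(str).str.upper())
    names, rows = [], []
    for gs in collection:
        mask = uni_upper.isin(set(gs.genes))
        if int(mask.sum()) < min_size:
            continue
        names.append(gs.name)
        rows.append(np.asarray(mask))
    if not rows:
        return [], np.zeros((0, len(universe)), dtype=bool)
    return names, np.vstack(rows)


def sample_landscape(
    gene_z: pd.DataFrame,
    collection: GeneSetCollection,
    groups: pd.Series | None = None,
    min_size: int = MIN_SET_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample gene-set scores (the functional landscape).

    Each sample's within-sample z vector serves as its own metric; each
    retained set gets Z = (Sm - mu) sqrt(m) / delta per sample, with mu and
    delta the per-sample column moments. Returns the sets x samples score
    matrix and, when ``groups`` is given, the sets x groups matrix of
    group-averaged scores.
    """
    names, member = _membership_matrix(collection, gene_z.index, min_size)
    arr = gene_z.to_numpy(float)
    mu = arr.mean(axis=0)
    delta = arr.std(axis=0)
    if (delta == 0).any():
        raise ValueError("constant per-sample metric column; landscape undefined")
    m = member.sum(axis=1).astype(float)  # per-set effective size
    sums = member.astype(float) @ arr
    s_mean = sums / m[:, None]
    z = (s_mean - mu[None, :]) * np.sqrt(m)[:, None] / delta[None, :]
    scores = pd.DataFrame(z, index=pd.Index(names, name="set"), columns=gene_z.columns)
    group_view = None
    if groups is not None:
        groups = groups.reindex(gene_z.columns)
        group_view = scores.T.groupby(groups, sort=False).mean().T
    return scores, group_view


def score_signature_in_dataset(
    matrix: ExpressionMatrix,
    contrasts: Mapping[str, tuple[str, str]],
    signature: GeneSet,
    background: GeneSetCollection,
    min_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Score a signature against contrasts of an (external-style) dataset.

    For each contrast label -> (group, baseline), a simple difference metric
    is computed on gene-collapsed log2 values and the signature is scored
    inside the union of the background collection and the signature itself.
    Returns one row per contrast with the signature's Z, p, effective size,
    rank among all reported sets (1 = highest Z) and the number of reported
    sets. A signature whose effective size falls below ``min_size`` in the
    dataset's universe gets ``reported = False`` and NaN scores.
    """
    if matrix.scale != "log2":
        raise ValueError("expects a log2-scale matrix")
    gene_log2 = collapse_to_genes(matrix.values, matrix.probe_annotations)
    combined = background.union([signature]) if signature.name not in background else background
    rows = []
    for label, (group, baseline) in contrasts.items():
        metric = difference_metric(
            gene_log2, matrix.samples_in_group(group), matrix.samples_in_group(baseline), label=label
        )
        table = score_collection(metric, combined, min_size=min_size, p_cutoff=P_CUTOFF)
        hit = table[table["set"] == signature.name]
        if len(hit) == 0:
            rows.append(
                {"contrast": label, "z": np.nan, "p": np.nan, "m": 0, "rank": np.nan,
                 "n_sets": len(table), "reported": False}
            )
            continue
        rank = int(hit.index[0]) + 1  # table sorted by z descending
        rows.append(
            {
                "contrast": label,
                "z": float(hit["z"].iloc[0]),
                "p": float(hit["p"].iloc[0]),
                "m": int(hit["m"].iloc[0]),
                "rank": rank,
                "n_sets": len(table),
                "reported": True,
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
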