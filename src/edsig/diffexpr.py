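"""Three-criterion differential expression with a detection gate.

A probe is significantly differentially expressed between two groups when
(i) its two-sided Welch t-test p-value is <= 0.01, (ii) its Benjamini-
Hochberg false-discovery rate q is <= 0.1, and (iii) its fold change —
the ratio of geometric means, i.e. 2^(difference of mean log2 values) — is
>= 1.5 or <= 1/1.5. A probe is tested at all only if, in the group with the
higher average expression, at least 80% of samples have detection p < 0.01;
this avoids calls driven by background noise and shrinks the testing
universe for the FDR step. The BH correction is therefore computed over
gated probes only, within each contrast separately.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LOG2, ExpressionMatrix

P_MAX = 0.01
Q_MAX = 0.1
FC_MIN = 1.5
DETECT_P = 0.01
DETECT_FRACTION = 0.8


def detection_gate(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    detected_frac_a: np.ndarray,
    detected_frac_b: np.ndarray,
    fraction: float = DETECT_FRACTION,
) -> np.ndarray:
    """Vectorized detection gate.

    True where the group with the larger mean has detected fraction >=
    ``fraction``. A tie in group means is treated symmetrically: the probe
    is gated in if either group meets the detection requirement.
    """
    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    fa = np.asarray(detected_frac_a, float)
    fb = np.asarray(detected_frac_b, float)
    higher_is_a = mean_a > mean_b
    tie = mean_a == mean_b
    gated = np.where(higher_is_a, fa >= fraction, fb >= fraction)
    return np.where(tie, (fa >= fraction) | (fb >= fraction), gated)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    df is Welch–Satterthwaite. If both groups have zero variance and equal
    means, (0, df, 1) is returned by convention; zero variance in both
    groups with unequal means leaves the statistic undefined and raises.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, df, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test on probes x samples blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = sa + sb
    degenerate = denom == 0
    if degenerate.any():
        if (degenerate & (ma != mb)).any():
            raise ValueError("zero variance in both groups with unequal means")
    safe = np.where(degenerate, 1.0, denom)
    t = np.where(degenerate, 0.0, (ma - mb) / np.sqrt(safe))
    with np.errstate(invalid="ignore", divide="ignore"):
        df = safe**2 / np.where(
            degenerate, 1.0, sa**2 / (na - 1) + sb**2 / (nb - 1)
        )
    df = np.where(degenerate, float(na + nb - 2), df)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clipped to 1;
    a monotone nondecreasing function of p.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def geometric_fold_change(mean_a_log2, mean_b_log2):
    """Ratio of geometric means from mean log2 values: 2^(mean_a - mean_b)."""
    return np.power(2.0, np.asarray(mean_a_log2, float) - np.asarray(mean_b_log2, float))


def call_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    probes: Sequence[str] | None = None,
    detect_p: float = DETECT_P,
    detect_fraction: float = DETECT_FRACTION,
    p_max: float = P_MAX,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
) -> pd.DataFrame:
    """Run the full three-criterion caller for one group contrast.

    Returns one row per probe (in the supplied universe) with group means,
    fold change (of group_a over group_b, linear scale), Welch t/df/p, BH q
    over gated probes, the ``tested`` gate flag, the ``significant`` call
    and the regulation ``direction`` relative to ``group_a``. Probes failing
    the gate have NaN statistics.
    """
    if matrix.scale != LOG2:
        raise ValueError("call_de expects a log2-scale matrix")
    samples_a = matrix.samples_in_group(group_a)
    samples_b = matrix.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"groups need >= 2 samples ({group_a}: {len(samples_a)}, {group_b}: {len(samples_b)})")
    if set(samples_a) & set(samples_b):
        raise ValueError("groups overlap")

    sub = matrix if probes is None else matrix.subset_probes(probes)
    a = sub.values[samples_a].to_numpy(float)
    b = sub.values[samples_b].to_numpy(float)
    det_a = (sub.detection_p[samples_a].to_numpy() < detect_p).mean(axis=1)
    det_b = (sub.detection_p[samples_b].to_numpy() < detect_p).mean(axis=1)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    tested = detection_gate(mean_a, mean_b, det_a, det_b, fraction=detect_fraction)

    n = sub.n_probes
    t = np.full(n, np.nan)
    df = np.full(n, np.nan)
    p = np.full(n, np.nan)
    q = np.full(n, np.nan)
    if tested.any():
        t_g, df_g, p_g = _welch_arrays(a[tested], b[tested])
        t[tested], df[tested], p[tested] = t_g, df_g, p_g
        q[tested] = bh_fdr(p_g)

    fc = geometric_fold_change(mean_a, mean_b)
    passes_fc = (fc >= fc_min) | (fc <= 1.0 / fc_min)
    with np.errstate(invalid="ignore"):
        significant = tested & (p <= p_max) & (q <= q_max) & passes_fc

    return pd.DataFrame(
        {
            "gene": sub.probe_annotations.to_numpy(),
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "fold_change": fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "tested": tested,
            "significant": significant,
            "direction": np.where(mean_a >= mean_b, "up", "down"),
        },
        index=sub.probes,
    )


def significant_genes(de: pd.DataFrame, direction: str = "both") -> list[str]:
    """Collapse significant probes to a sorted, deduplicated gene list.

    A gene is significant if any of its probes is; ``direction`` restricts
    to "up" or "down" calls (relative to the contrast's first group).
    """
    mask = de["significant"].to_numpy(bool)
    if direction in ("up", "down"):
        mask &= (de["direction"] == direction).to_numpy()
    elif direction != "both":
        raise ValueError("direction must be 'up', 'down' or 'both'")
    genes = de.loc[mask, "gene"].dropna().astype(str)
    return sorted(set(genes))


def venn_partition(gene_lists: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], list[str]]:
    """Partition the union of significant-gene lists into Venn regions.

    Keys are tuples of the contrast names a gene belongs to (in input
    order); all 2^k - 1 nonempty-membership regions are returned, possibly
    with empty gene lists, and region sizes sum to the union size.
    """
    names = list(gene_lists)
    if len(names) < 2:
        raise ValueError("venn_partition needs at least 2 lists")
    sets = {name: set(gene_lists[name]) for name in names}
    regions: dict[tuple[str, ...], list[str]] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = sorted(inside - outside)
    return regions
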