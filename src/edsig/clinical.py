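"""Associating signature biomarkers with hemodynamic severity.

Implements the correlation analysis between a surrogate biomarker's log2
expression and right-heart-catheterization covariates (RAmean, CI, PVRI,
PA saturation): the Pearson product-moment coefficient with the customary
t-test (t = r sqrt(n-2) / sqrt(1-r^2), df = n-2), restricted to subjects
whose catheterization fell within a four-month window of the blood draw.
Also provides 84% confidence intervals for group means (whose non-overlap
approximates a 0.05-level mean difference), dichotomization of cardiac
index at 2.2 L/min/m^2, and the 2^-ddCt relative quantification used for
qPCR validation of array results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LOG2, ExpressionMatrix

WINDOW_DAYS = 120.0  # "four months" as 4 x 30 days
CI_THRESHOLD = 2.2
CI_LEVEL = 0.84
CONTROL_GENES = ("GAPDH", "ACTB", "PGK1")


@dataclass
class CorrelationResult:
    """Pearson r with its t-test against rho = 0."""

    r: float
    n: int
    t: float
    df: int
    p: float
    exact_fit: bool = False


def window_filter(
    table: pd.DataFrame, max_days: float = WINDOW_DAYS, covariate: str | None = None
) -> list[str]:
    """Subjects whose catheterization-to-draw offset is within the window.

    Keeps subjects with 0 <= days_cath_to_draw <= ``max_days``; when a
    ``covariate`` is named, that covariate must also be available (non-NA).
    """
    days = pd.to_numeric(table["days_cath_to_draw"], errors="coerce")
    keep = (days >= 0) & (days <= max_days)
    if covariate is not None:
        keep &= table[covariate].notna()
    return list(table.index[keep.fillna(False)])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.clip(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0))


def correlation_test(r: float, n: int) -> CorrelationResult:
    """The customary t-test of rho = 0 from (r, n) alone.

    t = r sqrt(n-2) / sqrt(1-r^2) referred to Student's t with n-2 degrees
    of freedom (two-sided). |r| = 1 is an exact fit: p is reported as 0
    with the ``exact_fit`` flag set.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| > 1")
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=float(r), n=n, t=np.inf * np.sign(r), df=df, p=0.0, exact_fit=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=float(r), n=n, t=float(t), df=df, p=float(p))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r plus its significance test in one call."""
    x = np.asarray(x, float)
    return correlation_test(pearson_r(x, y), len(x))


def biomarker_hemodynamics(
    matrix: ExpressionMatrix,
    surrogate: str,
    clinical: pd.DataFrame,
    covariates: Sequence[str],
    group: str,
    max_days: float = WINDOW_DAYS,
) -> pd.DataFrame:
    """Correlate a surrogate biomarker with hemodynamic covariates.

    ``surrogate`` may be a probe id or a gene symbol (resolved to the probe
    with the highest mean expression). Within the stated group, subjects
    passing the catheterization window with the covariate available are
    used; covariates with fewer than 3 usable subjects are skipped with a
    warning. Correlations are computed on log2 expression.
    """
    if matrix.scale != LOG2:
        raise ValueError("expects a log2-scale matrix")
    probe = _resolve_probe(matrix, surrogate)
    expr = matrix.values.loc[probe]
    rows = []
    group_subjects = [s for s in clinical.index if clinical.loc[s, "group"] == group]
    for cov in covariates:
        subjects = [
            s
            for s in window_filter(clinical.loc[group_subjects], max_days=max_days, covariate=cov)
            if s in expr.index
        ]
        if len(subjects) < 3:
            warnings.warn(f"covariate {cov}: fewer than 3 usable subjects in {group}; skipped", stacklevel=2)
            continue
        res = correlate(expr.loc[subjects], pd.to_numeric(clinical.loc[subjects, cov]))
        rows.append(
            {"covariate": cov, "group": group, "n": res.n, "r": res.r, "t": res.t, "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows, columns=["covariate", "group", "n", "r", "t", "df", "p"])


def _resolve_probe(matrix: ExpressionMatrix, surrogate: str) -> str:
    if surrogate in matrix.probes:
        return surrogate
    symbols = matrix.probe_annotations.dropna().astype(str).str.upper()
    hits = symbols.index[symbols == surrogate.upper()]
    if len(hits) == 0:
        raise KeyError(f"surrogate {surrogate!r} matches no probe or gene symbol")
    if len(hits) == 1:
        return hits[0]
    means = matrix.values.loc[hits].mean(axis=1)
    return means.sort_values(ascending=False).index[0]


def group_ci84(values: Sequence[float], level: float = CI_LEVEL) -> tuple[float, float, float]:
    """Mean and t-based confidence interval for one group.

    At the default 84% level, non-overlap of two groups' intervals is an
    approximate indicator of a significant mean difference at the 0.05
    level. Uses the t distribution (groups as small as 8 occur), so the
    large-n half-width tends to the z quantile 1.4051 x SE.
    """
    arr = np.asarray(values, float)
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    se = arr.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf((1.0 + level) / 2.0, n - 1) * se
    return float(mean), float(mean - half), float(mean + half)


def dichotomize_ci(table: pd.DataFrame, threshold: float = CI_THRESHOLD) -> pd.Series:
    """Stratify subjects by cardiac index: low (< threshold) vs high.

    The boundary value goes to the high stratum (the poor-prognosis stratum
    is defined as CI strictly below the cut). Subjects with missing CI are
    left unassigned (NA).
    """
    ci = pd.to_numeric(table["CI"], errors="coerce")
    out = pd.Series(pd.NA, index=table.index, dtype=object)
    out[ci < threshold] = "low"
    out[ci >= threshold] = "high"
    return out


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    targets: Sequence[str],
    calibrator: str,
    control_genes: Sequence[str] = CONTROL_GENES,
) -> pd.DataFrame:
    """2^-ddCt relative quantification against endogenous controls.

    dCt = Ct_target - mean(Ct of control genes) per sample; ddCt subtracts
    the calibrator sample's dCt; the relative quantity is 2^-ddCt (1 for
    the calibrator by construction). Missing control Ct values are an
    error — the normalizer would silently shift otherwise.
    """
    missing = [g for g in control_genes if g not in ct_table.columns]
    if missing:
        raise ValueError(f"control genes missing from Ct table: {missing}")
    if calibrator not in ct_table.index:
        raise KeyError(f"calibrator sample {calibrator!r} not in Ct table")
    controls = ct_table[list(control_genes)]
    if controls.isna().any().any():
        raise ValueError("missing Ct value for a control gene")
    norm = controls.mean(axis=1)
    out = {}
    for gene in targets:
        if gene not in ct_table.columns:
            raise KeyError(f"target {gene!r} not in Ct table")
        dct = ct_table[gene] - norm
        ddct = dct - dct.loc[calibrator]
        out[gene] = np.power(2.0, -ddct)
    return pd.DataFrame(out, index=ct_table.index)
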