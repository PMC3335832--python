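"""Preprocessing of probe-intensity matrices.

The pipeline entry point is a raw (background-uncorrected) intensity matrix.
Preprocessing follows the bead-array convention used throughout this
package: every sample is scaled so its median intensity is 256 (2^8), values
are log2 transformed, probes are restricted to those detected (detection
p < 0.01) in at least one sample and carrying a gene symbol, and two
z-transformations are provided — within-sample (columns standardized over a
probe subset, the input for per-sample gene-set scoring) and across-samples
(rows standardized, the heatmap/clustering normalization).

Both z-transformations use the population (divide-by-N) standard deviation;
the same convention is used for the gene-set metric standardization so the
scores are internally consistent.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import INTENSITY, LOG2, ExpressionMatrix

DEFAULT_MEDIAN_TARGET = 256.0
DEFAULT_DETECTION_P = 0.01
LOG_FLOOR = 1.0


def median_scale(matrix: ExpressionMatrix, target: float = DEFAULT_MEDIAN_TARGET) -> ExpressionMatrix:
    """Scale each sample column so its median intensity equals ``target``.

    Requires the intensity scale. Raises if any sample has a non-positive
    median (such a column cannot be brought to a positive target by scaling).
    """
    if matrix.scale != INTENSITY:
        raise ValueError("median_scale expects the intensity scale")
    medians = matrix.values.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])[:5]
        raise ValueError(f"non-positive median intensity in samples {bad}")
    scaled = matrix.values * (target / medians)
    return matrix.with_values(scaled, INTENSITY)


def log2_transform(matrix: ExpressionMatrix, floor: float = LOG_FLOOR) -> ExpressionMatrix:
    """Log2-transform an intensity matrix.

    Intensities below ``floor`` (default 1.0) are floored first: with no
    background correction, small positive intensities occur and would
    otherwise map to large negative logs. Non-positive floors are rejected.
    """
    if matrix.scale != INTENSITY:
        raise ValueError("log2_transform expects the intensity scale")
    if floor <= 0:
        raise ValueError("floor must be positive")
    arr = matrix.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cannot log-transform a matrix with missing values")
    floored = np.maximum(arr, floor)
    out = pd.DataFrame(np.log2(floored), index=matrix.probes, columns=matrix.samples)
    return matrix.with_values(out, LOG2)


def expressed_probe_filter(
    matrix: ExpressionMatrix,
    detect_p: float = DEFAULT_DETECTION_P,
    min_samples: int = 1,
    require_symbol: bool = True,
) -> list[str]:
    """Probes detected (p < ``detect_p``) in at least ``min_samples`` samples.

    With ``require_symbol`` (default), probes lacking a gene symbol are also
    dropped. Returns probe ids in matrix order; an empty result is allowed.
    """
    detected = (matrix.detection_p.to_numpy() < detect_p).sum(axis=1) >= min_samples
    keep = detected
    if require_symbol:
        has_symbol = matrix.probe_annotations.notna().to_numpy()
        keep = keep & has_symbol
    return list(matrix.probes[keep])


def zscore_within_sample(
    matrix: ExpressionMatrix, probes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Standardize each sample column to mean 0, SD 1 over a probe subset.

    Uses the population SD. A constant column is degenerate for this
    normalization and raises.
    """
    if matrix.scale != LOG2:
        raise ValueError("zscore_within_sample expects log2 values")
    values = matrix.values if probes is None else matrix.values.loc[list(probes)]
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)  # ddof=0
    if (sd == 0).any():
        bad = list(values.columns[sd == 0])[:5]
        raise ValueError(f"constant sample column(s), cannot z-score: {bad}")
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)


def zscore_across_samples(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each probe row to mean 0, SD 1 (population SD).

    Constant rows carry no signal; they are emitted as all-zero rows with a
    warning (the heatmap convention) rather than raising, so display-level
    callers keep the full probe set. Idempotent: rows already standardized
    are returned unchanged.
    """
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant probe row(s) emitted as zeros",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (arr - mu) / safe_sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=values.index, columns=values.columns)
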