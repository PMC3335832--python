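import numpy as np
import pandas as pd
import pytest

from edsig import preprocess
from edsig.matrix import ExpressionMatrix
from edsig.synth import CohortConfig, ModuleSpec, generate_cohort


def tiny_matrix(values, groups=None, detection=None, symbols=None, scale="log2"):
    """Hand-built ExpressionMatrix from a dict probe -> list of values."""
    frame = pd.DataFrame(values).T
    n = frame.shape[1]
    frame.columns = [f"s{i}" for i in range(n)]
    det = (
        pd.DataFrame(detection).T.set_axis(frame.columns, axis=1)
        if detection is not None
        else pd.DataFrame(0.0, index=frame.index, columns=frame.columns)
    )
    ann = pd.Series(symbols) if symbols is not None else pd.Series(
        {p: f"G_{p}" for p in frame.index}
    )
    samples = pd.DataFrame(
        {"group": groups if groups is not None else ["A"] * n}, index=frame.columns
    )
    return ExpressionMatrix(
        values=frame,
        detection_p=det,
        probe_annotations=ann,
        sample_annotations=samples,
        scale=scale,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (140 subjects x 20000 probes), seed 7."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_prep(default_cohort):
    """Preprocessed default cohort: median-scaled, log2, expressed probes."""
    matrix, clinical, truth = default_cohort
    scaled = preprocess.log2_transform(preprocess.median_scale(matrix))
    prep = scaled.subset_probes(preprocess.expressed_probe_filter(scaled))
    return prep, clinical, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort for structural tests (2000 probes, 2 groups)."""
    specs = [
        ModuleSpec("EDS", 40, {"IPAH": 0.6, "Control": 0.02}, 2.0, 0.8),
        ModuleSpec("PL", 60, {"IPAH": 0.4, "Control": 0.05}, 1.5, 0.7, {"EDS": 0.6}),
    ]
    cfg = CohortConfig(
        seed=11,
        group_sizes={"Control": 20, "IPAH": 20},
        n_probes=2000,
        module_specs=specs,
        hemodynamic_coupling={"IPAH": {"RAmean": 0.776}},
    )
    return cfg, generate_cohort(cfg)
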