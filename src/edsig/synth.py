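"""Seeded synthetic PBMC cohort generator.

Emulates the statistical structure of a five-group bead-array cohort of
pulmonary-hypertension and scleroderma patients plus healthy controls:

* per-probe log2 intensities = probe baseline + planted module activation +
  Gaussian noise, anti-logged to the intensity scale on emission so the
  median-scaling / log2 preprocessing is exercised end to end;
* planted correlated gene modules — an erythroid-differentiation signature
  (EDS), a platelet signature (PL) coupled to it, immune-response up/down
  modules, an immature-neutrophil signature, and a sex-linked module — each
  with group-specific penetrance (the fraction of subjects in which the
  module is active) and graded, continuous activation amplitudes;
* Illumina-style detection p-values separating expressed probes from
  unexpressed background probes;
* hemodynamic covariates (RAmean, CI, PVRI, PA saturation, 6MWD) coupled to
  the EDS activation amplitude in the IPAH group but decoupled in SSc-PAH,
  plus NYHA class and a catheterization-to-blood-draw offset.

Everything is driven by one integer seed; identical configuration and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

PH_GROUPS = ("IPAH", "SSc-PAH", "SSc-PH-ILD")
DISEASE_GROUPS = ("SSc", "IPAH", "SSc-PAH", "SSc-PH-ILD")

DEFAULT_GROUP_SIZES = {
    "Control": 41,
    "SSc": 19,
    "IPAH": 30,
    "SSc-PAH": 42,
    "SSc-PH-ILD": 8,
}

#: fraction of female subjects per group (cohort demographics)
DEFAULT_FEMALE_FRACTION = {
    "Control": 34 / 41,
    "SSc": 1.0,
    "IPAH": 25 / 30,
    "SSc-PAH": 33 / 42,
    "SSc-PH-ILD": 6 / 8,
}

#: per-group hemodynamic baselines as (mean, SD); units: RAmean mmHg,
#: CI L/min/m^2, PVRI dyn.s.cm^-5.m^2, PA_sat %, sixMWD distance (feet)
HEMODYNAMIC_BASELINES: dict[str, dict[str, tuple[float, float]]] = {
    "IPAH": {
        "RAmean": (7.7, 4.2),
        "CI": (2.61, 0.69),
        "PVRI": (1214.0, 573.0),
        "PA_sat": (66.1, 9.1),
        "sixMWD": (1383.0, 392.0),
    },
    "SSc-PAH": {
        "RAmean": (7.9, 4.4),
        "CI": (2.66, 0.74),
        "PVRI": (955.0, 556.0),
        "PA_sat": (67.1, 8.0),
        "sixMWD": (1091.0, 340.0),
    },
    "SSc-PH-ILD": {
        "RAmean": (7.5, 3.8),
        "CI": (2.88, 0.80),
        "PVRI": (1042.0, 610.0),
        "PA_sat": (66.9, 6.7),
        "sixMWD": (891.0, 378.0),
    },
}

HEMODYNAMIC_COVARIATES = ("RAmean", "CI", "PVRI", "PA_sat", "sixMWD")

#: target correlation between each covariate and the EDS activation
#: amplitude; severity couples in IPAH and is absent in SSc-PAH/SSc-PH-ILD
DEFAULT_HEMODYNAMIC_COUPLING: dict[str, dict[str, float]] = {
    "IPAH": {"RAmean": 0.776, "PVRI": 0.752, "PA_sat": -0.71, "CI": -0.449},
    "SSc-PAH": {},
    "SSc-PH-ILD": {},
}

#: NYHA functional class distribution (classes I..IV) per PH group
NYHA_DISTRIBUTION = {
    "IPAH": (7 / 30, 16 / 30, 6 / 30, 1 / 30),
    "SSc-PAH": (2 / 42, 22 / 42, 17 / 42, 1 / 42),
    "SSc-PH-ILD": (0.0, 1 / 8, 7 / 8, 0.0),
}

#: curated leading symbols for the planted erythroid and platelet modules;
#: remaining members get generated symbols
_EDS_SYMBOLS = ("ALAS2", "AHSP", "HBA2", "HBD", "HBG1", "HBG2", "HBM", "HBQ1", "CA2", "EPB42")
_PL_SYMBOLS = ("PF4", "PPBP", "ITGA2B", "GP9", "TUBB1")

#: maximum days between right-heart catheterization and blood draw
DRAW_OFFSET_MAX_DAYS = 300.0


@dataclass
class ModuleSpec:
    """One planted correlated gene module.

    ``penetrance`` maps group label -> fraction of that group's subjects in
    which the module is active; active subjects receive a graded activation
    amplitude (gamma-distributed with mean ``amplitude_log2``), so module
    levels vary continuously among carriers. ``within_module_corr`` is the
    target pairwise sample-correlation of member probes across the cohort;
    ``cross_module_corr`` maps the name of an earlier module to a target
    correlation between the two modules' subject-amplitude vectors.
    ``sex_linked`` modules ignore penetrance and activate in male subjects.
    """

    name: str
    probe_count: int
    penetrance: dict[str, float] = field(default_factory=dict)
    amplitude_log2: float = 2.0
    within_module_corr: float = 0.8
    cross_module_corr: dict[str, float] = field(default_factory=dict)
    sex_linked: bool = False

    def validate(self) -> None:
        if self.probe_count < 1:
            raise ValueError(f"module {self.name}: probe_count must be >= 1")
        for g, p in self.penetrance.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"module {self.name}: penetrance for {g} outside [0, 1]")
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValueError(f"module {self.name}: within_module_corr outside (0, 1)")
        for other, r in self.cross_module_corr.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"module {self.name}: cross correlation with {other} outside (-1, 1)")


def default_module_specs() -> list[ModuleSpec]:
    """The default planted-module panel.

    Sizes mirror the expanded signatures of the motivating cohort (EDS 169
    probes, platelet 456); immune-response modules mirror the seed-cluster
    sizes (81 up, 58 down). The EDS is penetrant in half of the PAH groups,
    nearly all SSc-PH-ILD subjects, and nearly absent from SSc and controls;
    the platelet module tracks the EDS with a target amplitude correlation
    of 0.6 across subjects.
    """
    disease_pen = {g: 0.9 for g in DISEASE_GROUPS} | {"Control": 0.05}
    return [
        ModuleSpec(
            "EDS",
            169,
            penetrance={"IPAH": 0.5, "SSc-PAH": 0.5, "SSc-PH-ILD": 0.9, "SSc": 0.1, "Control": 0.02},
            amplitude_log2=2.0,
            within_module_corr=0.8,
        ),
        ModuleSpec(
            "PL",
            456,
            penetrance={"IPAH": 0.4, "SSc-PAH": 0.4, "SSc-PH-ILD": 0.6, "SSc": 0.15, "Control": 0.05},
            amplitude_log2=1.5,
            within_module_corr=0.7,
            cross_module_corr={"EDS": 0.6},
        ),
        ModuleSpec("IR_UR", 81, penetrance=disease_pen, amplitude_log2=1.0, within_module_corr=0.6),
        ModuleSpec("IR_DR", 58, penetrance=disease_pen, amplitude_log2=-1.0, within_module_corr=0.6),
        ModuleSpec("INS", 40, penetrance={g: 0.3 for g in DEFAULT_GROUP_SIZES}, amplitude_log2=1.5, within_module_corr=0.7),
        ModuleSpec("SEX", 10, amplitude_log2=2.0, within_module_corr=0.8, sex_linked=True),
    ]


@dataclass
class CohortConfig:
    """Full cohort-simulation configuration.

    ``noise_sd`` is the per-probe log2-scale residual SD (0.3, a typical
    within-group probe-level variability for processed bead arrays);
    ``baseline_log2_mean`` locates expressed-probe baselines around the
    post-scaling median of 8; ``detection_background_fraction`` is the
    fraction of probes that are unexpressed background noise. A seed is
    mandatory — there is no implicit nondeterminism.
    """

    seed: int
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_probes: int = 20000
    module_specs: list[ModuleSpec] = field(default_factory=default_module_specs)
    noise_sd: float = 0.3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    detection_background_fraction: float = 0.3
    hemodynamic_coupling: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(c) for g, c in DEFAULT_HEMODYNAMIC_COUPLING.items()}
    )
    female_fraction: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEMALE_FRACTION))
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g}: size must be >= 1")
        planted = sum(s.probe_count for s in self.module_specs)
        if planted > self.n_probes:
            raise ValueError(f"{planted} planted module probes exceed n_probes={self.n_probes}")
        names = [s.name for s in self.module_specs]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique (probe memberships are disjoint)")
        for s in self.module_specs:
            s.validate()
            for other, _ in s.cross_module_corr.items():
                if other not in names:
                    raise ValueError(f"module {s.name}: unknown cross-correlation target {other}")
        for g, cov in self.hemodynamic_coupling.items():
            for c, r in cov.items():
                if not -1.0 < r < 1.0:
                    raise ValueError(f"coupling {g}/{c} outside (-1, 1)")
        if not 0.0 <= self.detection_background_fraction < 1.0:
            raise ValueError("detection_background_fraction outside [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort.

    ``module_membership`` maps each planted probe to its (unique) module;
    ``subject_amplitudes`` is the subjects x modules activation matrix;
    ``planted_de_genes`` lists, per disease-vs-control contrast, the gene
    symbols planted as up- or down-regulated; ``covariate_couplings`` holds
    the configured covariate-vs-EDS-amplitude target correlations.
    """

    module_membership: dict[str, str]
    subject_amplitudes: pd.DataFrame
    planted_de_genes: dict[str, dict[str, list[str]]]
    covariate_couplings: dict[str, dict[str, float]]

    def probes_in_module(self, name: str) -> list[str]:
        return [p for p, m in self.module_membership.items() if m == name]

    def to_json(self, path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "subject_amplitudes": {
                "index": list(self.subject_amplitudes.index),
                "index_name": self.subject_amplitudes.index.name,
                "columns": list(self.subject_amplitudes.columns),
                "data": self.subject_amplitudes.to_numpy().tolist(),
            },
            "planted_de_genes": self.planted_de_genes,
            "covariate_couplings": self.covariate_couplings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        amp = payload["subject_amplitudes"]
        frame = pd.DataFrame(amp["data"], index=amp["index"], columns=amp["columns"])
        frame.index.name = amp.get("index_name")
        return cls(
            module_membership=payload["module_membership"],
            subject_amplitudes=frame,
            planted_de_genes=payload["planted_de_genes"],
            covariate_couplings=payload["covariate_couplings"],
        )


# ---------------------------------------------------------------------------
# amplitude machinery


def _mixture_amplitudes(
    rng: np.random.Generator, spec: ModuleSpec, groups: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Graded activation per subject: Bernoulli(penetrance) x gamma magnitude."""
    n = len(groups)
    if spec.sex_linked:
        return np.where(sex == "M", spec.amplitude_log2, 0.0).astype(float)
    pen = np.array([spec.penetrance.get(g, 0.0) for g in groups])
    active = rng.random(n) < pen
    mag = np.abs(spec.amplitude_log2)
    if mag == 0:
        return np.zeros(n)
    # shape 4 => CV 0.5: carriers span a graded range of activation levels
    draw = rng.gamma(shape=4.0, scale=mag / 4.0, size=n)
    return np.sign(spec.amplitude_log2) * active * draw


def _blend_to_target_corr(a_self: np.ndarray, a_other: np.ndarray, rho: float) -> np.ndarray:
    """Rebuild ``a_self`` so its realized correlation with ``a_other`` is rho.

    Gram–Schmidt construction: keep the mean/SD of ``a_self`` but compose its
    standardized part from the standardized ``a_other`` (weight rho) and the
    component of ``a_self`` orthogonal to it (weight sqrt(1-rho^2)).
    """
    mu, sd = a_self.mean(), a_self.std()
    if sd == 0 or a_other.std() == 0:
        return a_self
    z_o = (a_other - a_other.mean()) / a_other.std()
    resid = a_self - a_self.mean() - (a_self - a_self.mean()) @ z_o / len(z_o) * z_o
    rsd = resid.std()
    z_r = resid / rsd if rsd > 0 else np.zeros_like(resid)
    return mu + sd * (rho * z_o + np.sqrt(1.0 - rho**2) * z_r)


def _module_rows(
    rng: np.random.Generator,
    baseline: np.ndarray,
    amplitude: np.ndarray,
    within_corr: float,
    noise_sd: float,
) -> np.ndarray:
    """Member-probe rows achieving the target within-module correlation.

    The shared subject amplitude already induces correlation
    var(a)/(var(a)+v) between member probes at idiosyncratic noise variance
    v. The required v is var(a)(1-rho)/rho: when it exceeds noise_sd^2 the
    extra variance is added as independent probe noise; when it is smaller,
    part of the noise budget is made module-shared so the correlation still
    reaches the target.
    """
    k, n = len(baseline), len(amplitude)
    var_a = float(amplitude.var())
    if var_a == 0:
        noise = rng.normal(0.0, noise_sd, size=(k, n))
        return baseline[:, None] + amplitude[None, :] + noise
    v_req = var_a * (1.0 - within_corr) / within_corr
    if v_req >= noise_sd**2:
        noise = rng.normal(0.0, np.sqrt(v_req), size=(k, n))
    else:
        noise_var = noise_sd**2
        alpha = (within_corr * (var_a + noise_var) - var_a) / noise_var
        alpha = float(np.clip(alpha, 0.0, 1.0))
        shared = rng.normal(0.0, 1.0, size=n)
        idio = rng.normal(0.0, 1.0, size=(k, n))
        noise = noise_sd * (np.sqrt(alpha) * shared[None, :] + np.sqrt(1.0 - alpha) * idio)
    return baseline[:, None] + amplitude[None, :] + noise


# ---------------------------------------------------------------------------
# cohort assembly


def _module_symbols(spec: ModuleSpec, count: int) -> list[str]:
    curated = {"EDS": _EDS_SYMBOLS, "PL": _PL_SYMBOLS}.get(spec.name, ())
    syms = list(curated[:count])
    syms += [f"{spec.name.replace('_', '')}G{i:03d}" for i in range(len(syms), count)]
    return syms


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate one seeded cohort: expression + clinical table + truth.

    Returns the probe x sample :class:`ExpressionMatrix` on the intensity
    scale (strictly positive, un-normalized medians), the clinical covariate
    table, and the :class:`SyntheticTruth` bookkeeping object.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # subjects ------------------------------------------------------------
    groups: list[str] = []
    sample_ids: list[str] = []
    for g, n in config.group_sizes.items():
        groups += [g] * n
        sample_ids += [f"{g}_{i + 1:02d}" for i in range(n)]
    groups_arr = np.array(groups)
    n_samples = len(sample_ids)
    female_p = np.array([config.female_fraction.get(g, 0.5) for g in groups_arr])
    sex = np.where(rng.random(n_samples) < female_p, "F", "M")

    # module amplitudes ---------------------------------------------------
    amplitudes: dict[str, np.ndarray] = {}
    for spec in config.module_specs:
        a = _mixture_amplitudes(rng, spec, groups_arr, sex)
        for other, rho in spec.cross_module_corr.items():
            if other in amplitudes:
                a = _blend_to_target_corr(a, amplitudes[other], rho)
        amplitudes[spec.name] = a

    # probe layout: module blocks first, then expressed background, then
    # unexpressed background probes
    probe_ids = [f"ILMN_{i + 1:07d}" for i in range(config.n_probes)]
    membership: dict[str, str] = {}
    symbols = pd.Series(pd.NA, index=pd.Index(probe_ids, name="probe"), dtype=object)
    cursor = 0
    module_slices: dict[str, slice] = {}
    for spec in config.module_specs:
        sl = slice(cursor, cursor + spec.probe_count)
        module_slices[spec.name] = sl
        syms = _module_symbols(spec, spec.probe_count)
        for p, s in zip(probe_ids[sl], syms):
            membership[p] = spec.name
            symbols[p] = s
        cursor += spec.probe_count
    n_background = int(round(config.detection_background_fraction * config.n_probes))
    n_background = min(n_background, config.n_probes - cursor)
    n_expressed_bg = config.n_probes - cursor - n_background
    expressed_bg = slice(cursor, cursor + n_expressed_bg)
    unexpressed = slice(cursor + n_expressed_bg, config.n_probes)

    # expressed background symbols: ~8% of genes carry two probes, to
    # exercise probe->gene collapse downstream
    gene_idx = 0
    i = 0
    bg_probes = probe_ids[expressed_bg]
    while i < len(bg_probes):
        sym = f"GENE{gene_idx:05d}"
        symbols[bg_probes[i]] = sym
        if i + 1 < len(bg_probes) and (gene_idx % 12 == 0):
            symbols[bg_probes[i + 1]] = sym
            i += 1
        gene_idx += 1
        i += 1
    # unexpressed probes: 60% annotated, 40% symbol-less
    for j, p in enumerate(probe_ids[unexpressed]):
        if j % 5 < 3:
            symbols[p] = f"BKG{j:05d}"

    # expression ----------------------------------------------------------
    log2 = np.empty((config.n_probes, n_samples))
    base_expr = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_probes)
    base_unexpr = rng.normal(config.baseline_log2_mean - 3.0, 0.8, size=config.n_probes)
    for spec in config.module_specs:
        sl = module_slices[spec.name]
        log2[sl] = _module_rows(
            rng, base_expr[sl], amplitudes[spec.name], spec.within_module_corr, config.noise_sd
        )
    log2[expressed_bg] = base_expr[expressed_bg, None] + rng.normal(
        0.0, config.noise_sd, size=(n_expressed_bg, n_samples)
    )
    n_unexpr = config.n_probes - cursor - n_expressed_bg
    log2[unexpressed] = base_unexpr[unexpressed, None] + rng.normal(
        0.0, config.noise_sd, size=(n_unexpr, n_samples)
    )

    detection = np.empty_like(log2)
    detection[: unexpressed.start] = rng.uniform(0.0, 0.005, size=(unexpressed.start, n_samples))
    detection[unexpressed] = rng.uniform(0.02, 1.0, size=(n_unexpr, n_samples))

    intensities = np.power(2.0, log2)

    sample_index = pd.Index(sample_ids, name="sample")
    sample_ann = pd.DataFrame(
        {"group": groups_arr, "sex": sex, "subject_id": sample_ids}, index=sample_index
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(intensities, index=pd.Index(probe_ids, name="probe"), columns=sample_index),
        detection_p=pd.DataFrame(detection, index=pd.Index(probe_ids, name="probe"), columns=sample_index),
        probe_annotations=symbols,
        sample_annotations=sample_ann,
        scale="intensity",
    )

    # clinical ------------------------------------------------------------
    amp_frame = pd.DataFrame(amplitudes, index=sample_index)
    eds_like = config.module_specs[0].name if config.module_specs else None
    eds_amp = amp_frame[eds_like] if eds_like is not None else pd.Series(0.0, index=sample_index)
    clinical = generate_hemodynamics(eds_amp, sample_ann["group"], config, rng=rng)
    clinical["sex"] = sex

    # planted differential expression per disease-vs-control contrast:
    # modules whose penetrance gap times amplitude implies a detectable
    # group-mean log2 shift (>= 0.5)
    planted: dict[str, dict[str, list[str]]] = {}
    control = "Control"
    if control in config.group_sizes:
        for g in config.group_sizes:
            if g == control:
                continue
            contrast = f"{g}_vs_{control}"
            up: list[str] = []
            down: list[str] = []
            for spec in config.module_specs:
                if spec.sex_linked:
                    continue
                gap = spec.penetrance.get(g, 0.0) - spec.penetrance.get(control, 0.0)
                shift = gap * spec.amplitude_log2
                if abs(shift) >= 0.5:
                    target = up if shift > 0 else down
                    target += sorted(
                        {str(symbols[p]) for p in probe_ids[module_slices[spec.name]]}
                    )
            planted[contrast] = {"up": up, "down": down}

    truth = SyntheticTruth(
        module_membership=membership,
        subject_amplitudes=amp_frame,
        planted_de_genes=planted,
        covariate_couplings={g: dict(c) for g, c in config.hemodynamic_coupling.items()},
    )
    return matrix, clinical, truth


def generate_hemodynamics(
    amplitudes: pd.Series,
    groups: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hemodynamic covariates coupled to the signature activation amplitude.

    For each PH group and covariate with target correlation rho, the
    covariate is baseline_mean + baseline_SD * (rho * z + sqrt(1-rho^2) * e)
    where z is the group-standardized amplitude and e is independent
    standard-normal noise, so the population correlation with the amplitude
    equals rho exactly. Non-PH groups get no hemodynamics (NA), mirroring a
    cohort in which only PH subjects undergo catheterization. Also simulates
    NYHA class and a catheterization-to-draw offset drawn U(0, 300) days.

    When ``config.missing_rate`` > 0, that fraction of hemodynamic cells is
    blanked; the injected mask is stored in ``table.attrs["injected_missing"]``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if config.seed is not None else None)
    for g, cov in config.hemodynamic_coupling.items():
        for c, r in cov.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"coupling {g}/{c} outside (-1, 1)")

    index = amplitudes.index
    table = pd.DataFrame(index=index, columns=["group", *HEMODYNAMIC_COVARIATES, "NYHA", "days_cath_to_draw"], dtype=object)
    table["group"] = groups.to_numpy()
    for cov in HEMODYNAMIC_COVARIATES:
        table[cov] = np.nan
    table["days_cath_to_draw"] = np.nan

    for g in pd.unique(groups):
        if g not in HEMODYNAMIC_BASELINES:
            continue
        mask = (groups == g).to_numpy()
        n = int(mask.sum())
        if any(mask):
            amp = amplitudes.to_numpy(dtype=float)[mask]
            sd_amp = amp.std()
            z = (amp - amp.mean()) / sd_amp if sd_amp > 0 else np.zeros(n)
            coupling = config.hemodynamic_coupling.get(g, {})
            for cov, (mean, sd) in HEMODYNAMIC_BASELINES[g].items():
                rho = float(coupling.get(cov, 0.0))
                eps = rng.normal(0.0, 1.0, size=n)
                vals = mean + sd * (rho * z + np.sqrt(1.0 - rho**2) * eps)
                if cov == "PA_sat":
                    vals = np.clip(vals, 0.0, 100.0)
                elif cov in ("CI", "PVRI", "sixMWD"):
                    vals = np.maximum(vals, 0.1)
                table.loc[mask, cov] = vals
            probs = NYHA_DISTRIBUTION.get(g)
            if probs is not None:
                classes = rng.choice(np.array(["I", "II", "III", "IV"]), size=n, p=np.asarray(probs) / np.sum(probs))
                table.loc[mask, "NYHA"] = classes
            table.loc[mask, "days_cath_to_draw"] = rng.uniform(0.0, DRAW_OFFSET_MAX_DAYS, size=n)

    for cov in HEMODYNAMIC_COVARIATES + ("days_cath_to_draw",):
        table[cov] = pd.to_numeric(table[cov])

    if config.missing_rate > 0:
        mask = pd.DataFrame(False, index=index, columns=list(HEMODYNAMIC_COVARIATES))
        for cov in HEMODYNAMIC_COVARIATES:
            available = table[cov].notna().to_numpy()
            inject = available & (rng.random(len(index)) < config.missing_rate)
            table.loc[inject, cov] = np.nan
            mask[cov] = inject
        table.attrs["injected_missing"] = mask
    return table
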