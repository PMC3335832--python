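"""Config-driven pipeline runner.

One YAML (or JSON) file drives the full analysis: a ``stages`` list chosen
from simulate | preprocess | de | discover | enrich | landscape | clinical |
validate-external, a global ``seed``, and optional per-stage parameter
blocks. Stages execute in dependency order, write TSV/JSON artifacts into
the output directory, and a manifest records the seed and a sha256 checksum
of every artifact, so a re-run with the same config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import diffexpr, gse, preprocess, signature
from .io import (
    read_clinical,
    read_gmt,
    read_series_matrix,
    write_clinical,
    write_detection,
    write_gmt,
    write_probe_annotations,
    write_series_matrix,
)
from .matrix import ExpressionMatrix
from .synth import CohortConfig, ModuleSpec, default_module_specs, generate_cohort

logger = logging.getLogger("edsig")

KNOWN_STAGES = (
    "simulate",
    "preprocess",
    "de",
    "discover",
    "enrich",
    "landscape",
    "clinical",
    "validate-external",
)


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} did not parse to a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_config(cfg: Mapping[str, Any], seed: int) -> CohortConfig:
    params = dict(cfg.get("simulate", {}) or {})
    modules = params.pop("module_specs", None)
    kwargs: dict[str, Any] = {"seed": params.pop("seed", seed)}
    for key in (
        "group_sizes",
        "n_probes",
        "noise_sd",
        "baseline_log2_mean",
        "baseline_log2_sd",
        "detection_background_fraction",
        "hemodynamic_coupling",
        "female_fraction",
        "missing_rate",
    ):
        if key in params:
            kwargs[key] = params.pop(key)
    if params:
        raise PipelineError(f"unknown simulate parameters: {sorted(params)}")
    if modules is not None:
        kwargs["module_specs"] = [ModuleSpec(**m) for m in modules]
    else:
        kwargs["module_specs"] = default_module_specs()
    return CohortConfig(**kwargs)


def _require(ctx: dict, key: str, stage: str, needed_by: str):
    if key not in ctx:
        raise PipelineError(
            f"stage {needed_by!r} needs the output of stage {stage!r}; add it to the stage list"
        )
    return ctx[key]


def _random_background(universe: list[str], n_sets: int, rng: np.random.Generator) -> gse.GeneSetCollection:
    """Seeded random gene-set background drawn from the dataset's universe."""
    coll = gse.GeneSetCollection(source="random-background")
    genes = np.array(sorted(universe))
    for i in range(n_sets):
        size = int(rng.integers(15, 120))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        coll.add(gse.GeneSet(name=f"BG{i:04d}", description="random background set", genes=tuple(members)))
    return coll


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir=None) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(config)
    stages = list(cfg.get("stages", []))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    if not stages:
        raise PipelineError("config lists no stages")
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "edsig_run"))
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    ctx: dict[str, Any] = {}
    manifest: dict[str, Any] = {"seed": seed, "stages": {}, "config": _jsonable(cfg)}
    try:
        for stage in stages:
            logger.info("running stage %s", stage)
            outputs = _STAGE_FUNCS[stage](cfg, seed, out, ctx)
            manifest["stages"][stage] = {name: _sha256(path) for name, path in outputs.items()}
    finally:
        logger.removeHandler(handler)
        handler.close()

    from importlib.metadata import version, PackageNotFoundError

    try:
        manifest["version"] = version("edsig")
    except PackageNotFoundError:
        manifest["version"] = "unknown"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    config = _cohort_config(cfg, seed)
    matrix, clinical_table, truth = generate_cohort(config)
    ctx["raw"] = matrix
    ctx["clinical"] = clinical_table
    ctx["truth"] = truth
    paths = {
        "expression": out / "expression.tsv",
        "detection": out / "detection.tsv",
        "probes": out / "probes.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_series_matrix(matrix, paths["expression"])
    write_detection(matrix, paths["detection"])
    write_probe_annotations(matrix, paths["probes"])
    write_clinical(clinical_table, paths["clinical"])
    truth.to_json(paths["truth"])
    return paths


def _load_raw(cfg, out: Path, ctx):
    if "raw" in ctx:
        return ctx["raw"]
    expr = out / "expression.tsv"
    if not expr.exists():
        raise PipelineError("stage 'preprocess' needs the output of stage 'simulate' (expression.tsv missing)")
    matrix = read_series_matrix(expr, detection_path=out / "detection.tsv", probe_annotation_path=out / "probes.tsv")
    ctx["raw"] = matrix
    return matrix


def _stage_preprocess(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    params = dict(cfg.get("preprocess", {}) or {})
    detect_p = params.get("detect_p", preprocess.DEFAULT_DETECTION_P)
    matrix = _load_raw(cfg, out, ctx)
    scaled = preprocess.log2_transform(preprocess.median_scale(matrix))
    expressed = preprocess.expressed_probe_filter(scaled, detect_p=detect_p)
    prep = scaled.subset_probes(expressed)
    ctx["prep"] = prep
    paths = {
        "prep_expression": out / "prep_expression.tsv",
        "prep_detection": out / "prep_detection.tsv",
        "prep_probes": out / "prep_probes.tsv",
    }
    write_series_matrix(prep, paths["prep_expression"])
    write_detection(prep, paths["prep_detection"])
    write_probe_annotations(prep, paths["prep_probes"])
    return paths


def _load_prep(cfg, out: Path, ctx) -> ExpressionMatrix:
    if "prep" in ctx:
        return ctx["prep"]
    expr = out / "prep_expression.tsv"
    if not expr.exists():
        raise PipelineError("a downstream stage needs the output of stage 'preprocess' (prep_expression.tsv missing)")
    prep = read_series_matrix(
        expr, detection_path=out / "prep_detection.tsv", probe_annotation_path=out / "prep_probes.tsv"
    )
    ctx["prep"] = prep
    return prep


def _contrasts(cfg, prep: ExpressionMatrix) -> dict[str, tuple[str, str]]:
    configured = (cfg.get("de", {}) or {}).get("contrasts")
    if configured:
        return {f"{a}_vs_{b}": (a, b) for a, b in configured}
    groups = prep.group_labels()
    baseline = "Control" if "Control" in groups else groups[0]
    return {f"{g}_vs_{baseline}": (g, baseline) for g in groups if g != baseline}


def _stage_de(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    prep = _load_prep(cfg, out, ctx)
    contrasts = _contrasts(cfg, prep)
    paths: dict[str, Path] = {}
    up_lists: dict[str, list[str]] = {}
    down_lists: dict[str, list[str]] = {}
    for label, (a, b) in contrasts.items():
        result = diffexpr.call_de(prep, a, b)
        path = out / f"de_{label}.tsv"
        result.to_csv(path, sep="\t", na_rep="NA")
        paths[f"de_{label}"] = path
        up_lists[label] = diffexpr.significant_genes(result, "up")
        down_lists[label] = diffexpr.significant_genes(result, "down")
    ctx["de_up"] = up_lists
    ctx["de_down"] = down_lists
    if len(contrasts) >= 2:
        venn = {
            "up": {" & ".join(k): v for k, v in diffexpr.venn_partition(up_lists).items()},
            "down": {" & ".join(k): v for k, v in diffexpr.venn_partition(down_lists).items()},
        }
        path = out / "venn.json"
        with open(path, "w") as fh:
            json.dump(venn, fh, indent=1, sort_keys=True)
        paths["venn"] = path
    return paths


def _stage_discover(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    params = dict(cfg.get("discover", {}) or {})
    k = params.get("k", signature.DEFAULT_TOP_K)
    r_min = params.get("r_min", signature.DEFAULT_R_MIN)
    max_clusters = params.get("max_clusters", 6)
    min_size = params.get("min_size", 20)
    prep = _load_prep(cfg, out, ctx)

    sample_z = preprocess.zscore_within_sample(prep)
    row_z = preprocess.zscore_across_samples(sample_z)
    top = signature.rank_by_variance(prep.values, k=k)
    link, _leaves = signature.hierarchical_cluster(row_z.loc[top])
    clusters = signature.extract_seed_clusters(row_z.loc[top], link, min_size=min_size, max_clusters=max_clusters)

    collection = gse.GeneSetCollection(source="discovered-signatures")
    detail_rows = []
    models = []
    for i, cluster in enumerate(clusters, start=1):
        centroid = signature.signature_centroid(prep.values, cluster.probes)
        model = signature.expand_signature(
            prep.values, centroid, r_min=r_min, name=f"SIG{i}", seed_probes=cluster.probes
        )
        models.append(model)
        symbols = prep.probe_annotations.reindex(model.probes).dropna().astype(str)
        collection.add(
            gse.GeneSet(
                name=model.name,
                description=f"discovered cluster of {len(cluster)} seed probes",
                genes=tuple(dict.fromkeys(symbols)),
            )
        )
        for probe, r in model.members.items():
            detail_rows.append(
                {"signature": model.name, "probe": probe, "gene": prep.gene_symbol(probe), "r": r}
            )
    ctx["signatures"] = models
    ctx["signature_collection"] = collection
    paths = {"signatures_gmt": out / "signatures.gmt", "signature_detail": out / "signature_detail.tsv"}
    write_gmt(collection, paths["signatures_gmt"])
    pd.DataFrame(detail_rows, columns=["signature", "probe", "gene", "r"]).to_csv(
        paths["signature_detail"], sep="\t", index=False
    )
    return paths


def _collection_for(cfg, stage: str, prep: ExpressionMatrix, ctx, seed: int) -> gse.GeneSetCollection:
    params = dict(cfg.get(stage, {}) or {})
    if params.get("gmt"):
        coll = read_gmt(params["gmt"])
    else:
        universe = list(
            gse.collapse_to_genes(prep.values, prep.probe_annotations).index.astype(str)
        )
        rng = np.random.default_rng(seed + 17)
        coll = _random_background(universe, int(params.get("n_background", 100)), rng)
    if "signature_collection" in ctx:
        for gs in ctx["signature_collection"]:
            if gs.name not in coll:
                coll.add(gs)
    return coll


def _stage_enrich(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    prep = _load_prep(cfg, out, ctx)
    coll = _collection_for(cfg, "enrich", prep, ctx, seed)
    sample_z = preprocess.zscore_within_sample(prep)
    gene_z = gse.collapse_to_genes(sample_z, prep.probe_annotations)
    paths: dict[str, Path] = {}
    for label, (a, b) in _contrasts(cfg, prep).items():
        metric = gse.zratio_metric(gene_z, prep.samples_in_group(a), prep.samples_in_group(b), label=label)
        table = gse.score_collection(metric, coll)
        path = out / f"enrichment_{label}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[f"enrichment_{label}"] = path
    return paths


def _stage_landscape(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    prep = _load_prep(cfg, out, ctx)
    coll = _collection_for(cfg, "landscape", prep, ctx, seed)
    sample_z = preprocess.zscore_within_sample(prep)
    gene_z = gse.collapse_to_genes(sample_z, prep.probe_annotations)
    scores, group_view = gse.sample_landscape(gene_z, coll, groups=prep.groups())
    paths = {"landscape": out / "landscape.tsv", "landscape_groups": out / "landscape_groups.tsv"}
    scores.to_csv(paths["landscape"], sep="\t")
    group_view.to_csv(paths["landscape_groups"], sep="\t")
    return paths


def _stage_clinical(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    params = dict(cfg.get("clinical", {}) or {})
    surrogate = params.get("surrogate", "ALAS2")
    group = params.get("group", "IPAH")
    window_days = params.get("window_days", clin.WINDOW_DAYS)
    covariates = params.get("covariates", ["RAmean", "PVRI", "PA_sat", "CI"])
    prep = _load_prep(cfg, out, ctx)
    if "clinical" in ctx:
        table = ctx["clinical"]
    else:
        path = out / "clinical.tsv"
        if not path.exists():
            raise PipelineError("stage 'clinical' needs the output of stage 'simulate' (clinical.tsv missing)")
        table = read_clinical(path)
    result = clin.biomarker_hemodynamics(prep, surrogate, table, covariates, group, max_days=window_days)
    strata = clin.dichotomize_ci(table)
    paths = {
        "clinical_correlations": out / "clinical_correlations.tsv",
        "ci_strata": out / "ci_strata.tsv",
    }
    result.to_csv(paths["clinical_correlations"], sep="\t", index=False)
    strata.rename("ci_stratum").to_frame().to_csv(paths["ci_strata"], sep="\t", na_rep="NA")
    return paths


def _stage_validate_external(cfg, seed, out: Path, ctx) -> dict[str, Path]:
    """Score discovered signatures in an independently simulated cohort."""
    params = dict(cfg.get("validate-external", {}) or {})
    if "signature_collection" not in ctx or not len(ctx["signature_collection"]):
        raise PipelineError("stage 'validate-external' needs the output of stage 'discover'")
    ext_cfg = _cohort_config(cfg, seed)
    ext_cfg.seed = int(params.get("seed", seed + 1000))
    matrix, _, _ = generate_cohort(ext_cfg)
    scaled = preprocess.log2_transform(preprocess.median_scale(matrix))
    expressed = preprocess.expressed_probe_filter(scaled)
    ext = scaled.subset_probes(expressed)
    coll = _collection_for(cfg, "validate-external", ext, {}, seed + 1)
    contrasts = _contrasts(cfg, ext)
    frames = []
    for gs in ctx["signature_collection"]:
        table = gse.score_signature_in_dataset(ext, contrasts, gs, coll)
        table.insert(0, "signature", gs.name)
        frames.append(table.reset_index())
    result = pd.concat(frames, ignore_index=True)
    path = out / "external_scores.tsv"
    result.to_csv(path, sep="\t", index=False, na_rep="NA")
    return {"external_scores": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "discover": _stage_discover,
    "enrich": _stage_enrich,
    "landscape": _stage_landscape,
    "clinical": _stage_clinical,
    "validate-external": _stage_validate_external,
}
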