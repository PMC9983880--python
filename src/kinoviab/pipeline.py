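"""Staged pipeline runner with per-stage provenance manifests.

Stages (in pipeline order): synth -> preprocess -> impute -> assemble ->
cv / sweep / ablate -> enrich -> final -> predict -> validate.  Each stage
writes its outputs plus a manifest recording the SHA-256 of its inputs,
the config hash and the seeds in effect; a rerun with unchanged inputs is
skipped unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .enrichment import build_network, filter_network, resample_null
from .features import assemble_design, correlate_features, rank_and_select
from .modeling import ModelSpec, cross_validate, hyperparameter_sweep, \
    make_group_folds, ablation_run
from .predict import (compare_validation, fit_final_model, normalize_plate,
                      predict_untested, qc_filter)
from .preprocess import (densify_inhibition, drop_incomplete_lines,
                         impute_missing_concentrations, impute_proteomics,
                         prefix_features, truncate_outliers)
from .runconfig import RunConfig
from .synthetic import GroundTruth, SyntheticConfig, generate_bundle
from .viability import filter_growth_enhancing, impute_viability

logger = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "preprocess", "impute", "assemble", "cv", "sweep",
               "ablate", "enrich", "final", "predict", "validate"]

STAGE_DEPS = {
    "synth": [],
    "preprocess": ["synth"],
    "impute": ["synth"],
    "assemble": ["preprocess", "impute"],
    "cv": ["assemble"],
    "sweep": ["assemble"],
    "ablate": ["assemble"],
    "enrich": ["assemble", "synth"],
    "final": ["assemble"],
    "predict": ["final", "preprocess"],
    "validate": ["predict", "synth"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


class PipelineError(RuntimeError):
    pass


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.manifest.json"


def _write_manifest(outdir: Path, stage: str, config: RunConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seeds": config.seeds,
        "inputs": {str(p.relative_to(outdir)): _sha256(p) for p in inputs},
        "outputs": [str(p.relative_to(outdir)) for p in outputs],
    }
    _manifest_path(outdir, stage).write_text(json.dumps(manifest, indent=1))


def _can_skip(outdir: Path, stage: str, config: RunConfig) -> bool:
    """Up-to-date check against the stage's own manifest: config hash
    unchanged, every recorded input re-hashes to the same value, and every
    recorded output still exists."""
    mpath = _manifest_path(outdir, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    if manifest.get("config_hash") != _config_hash(config):
        return False
    for rel, digest in manifest.get("inputs", {}).items():
        p = outdir / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return all((outdir / o).exists() for o in manifest.get("outputs", []))


# --- stage bodies ----------------------------------------------------------

def _stage_synth(config: RunConfig, outdir: Path) -> tuple[list[Path],
                                                           list[Path]]:
    syn = dict(config.synthetic)
    syn.setdefault("seed", config.seeds.get("synthetic", 0))
    syn.setdefault("dose_grid", tuple(config.dose_grid))
    enrichment_strength = syn.pop("enrichment_strength", 5.0)
    network_p0 = syn.pop("network_p0", 0.02)
    bundle = generate_bundle(SyntheticConfig(**syn), enrichment_strength,
                             network_p0)
    outs = []
    kio.write_inhibition_records(bundle.inhibition_records,
                                 outdir / "inhibition_records.csv")
    outs.append(outdir / "inhibition_records.csv")
    for cls, df in bundle.omics.items():
        p = outdir / f"omics_{cls}.csv"
        kio.write_omics_matrix(df, p)
        outs.append(p)
    kio.write_params(bundle.dose_response, outdir / "dose_response.csv")
    outs.append(outdir / "dose_response.csv")
    kio.write_edge_list(bundle.network, outdir / "network.tsv")
    outs.append(outdir / "network.tsv")
    kio.write_annotation(bundle.annotation, outdir / "annotation.csv")
    outs.append(outdir / "annotation.csv")
    bundle.truth.to_json(outdir / "ground_truth.json")
    outs.append(outdir / "ground_truth.json")
    (outdir / "synth_universe.json").write_text(json.dumps({
        "compounds": bundle.config.compounds,
        "proteins": bundle.config.proteins,
        "genes": bundle.config.genes,
        "cell_lines": bundle.config.cell_lines}))
    outs.append(outdir / "synth_universe.json")
    return [], outs


def _stage_preprocess(config: RunConfig, outdir: Path):
    ins = [outdir / "inhibition_records.csv"] + \
        [outdir / f"omics_{c}.csv" for c in
         ("expression", "cnv", "proteomics", "dependency")
         if (outdir / f"omics_{c}.csv").exists()]
    records = kio.read_inhibition_records(ins[0])
    universe = json.loads((outdir / "synth_universe.json").read_text())
    profile = densify_inhibition(records, universe["compounds"],
                                 universe["proteins"], config.dose_grid)
    profile = impute_missing_concentrations(profile)
    profile, threshold = truncate_outliers(
        profile, config.flags["truncation_percentile"])
    kio.write_profile(profile, outdir / "profile.csv",
                      sidecar={"truncation_threshold": threshold,
                               "truncation_percentile":
                                   config.flags["truncation_percentile"]})
    raw = {}
    for cls in ("expression", "cnv", "proteomics", "dependency"):
        p = outdir / f"omics_{cls}.csv"
        if p.exists():
            raw[cls] = kio.read_omics_matrix(p)
    if "proteomics" in raw:
        raw["proteomics"] = impute_proteomics(raw["proteomics"])
    if "dependency" in raw:
        raw["dependency"] = drop_incomplete_lines(raw["dependency"])
    prefixed = prefix_features(raw)
    outs = [outdir / "profile.csv", outdir / "profile.csv.json"]
    for cls, df in prefixed.items():
        p = outdir / f"clean_{cls}.csv"
        kio.write_omics_matrix(df, p)
        outs.append(p)
    return ins + [outdir / "synth_universe.json"], outs


def _stage_impute(config: RunConfig, outdir: Path):
    ins = [outdir / "dose_response.csv"]
    params = kio.read_params(ins[0])
    kept, removed = filter_growth_enhancing(params, config.dose_grid)
    viab = impute_viability(kept, config.dose_grid,
                            clip_max=config.flags["clip_max"])
    kio.write_viability(viab, outdir / "viability.csv")
    removed.to_csv(outdir / "growth_removed.csv", index=False)
    return ins, [outdir / "viability.csv", outdir / "growth_removed.csv"]


def _omics_classes(config: RunConfig) -> tuple[str, ...]:
    return tuple(c for c in config.feature_classes if c != "inhibition")


def _load_assembled(config: RunConfig, outdir: Path):
    table = kio.read_feature_table(outdir / "features.csv")
    return table


def _stage_assemble(config: RunConfig, outdir: Path):
    ins = [outdir / "viability.csv", outdir / "profile.csv"]
    viab = kio.read_viability(ins[0])
    profile = kio.read_profile(outdir / "profile.csv")
    omics = {}
    for cls in _omics_classes(config):
        p = outdir / f"clean_{cls}.csv"
        ins.append(p)
        omics[cls] = kio.read_omics_matrix(p)
    table = assemble_design(viab, profile, omics,
                            classes=_omics_classes(config))
    kio.write_feature_table(table, outdir / "features.csv")
    return ins, [outdir / "features.csv", outdir / "features.csv.json"]


def _folds_for(config: RunConfig, table: pd.DataFrame):
    combos = sorted(set(zip(table["cell_line"], table["compound"])))
    return make_group_folds(combos, config.n_folds, config.seeds["fold"])


def _stage_cv(config: RunConfig, outdir: Path):
    ins = [outdir / "features.csv"]
    table = _load_assembled(config, outdir)
    folds = _folds_for(config, table)
    rows = []
    sel_rows = []
    for k in config.k_features:
        spec = ModelSpec(family="random_forest", n_features=k,
                         seed=config.seeds["model"])
        res = cross_validate(table, spec, folds,
                             include_dose=config.flags["include_dose"],
                             signed_ranking=config.flags["signed_ranking"],
                             r2_mode=config.flags["r2_convention"])
        rows.append(("random_forest", k, res.r2, res.rmse))
        for fold, sel in enumerate(res.fold_selections, start=1):
            for f in sel:
                sel_rows.append((k, fold, f))
    base = cross_validate(table, ModelSpec(family="baseline_dose"), folds,
                          r2_mode=config.flags["r2_convention"])
    rows.append(("baseline_dose", 0, base.r2, base.rmse))
    metrics = pd.DataFrame(rows, columns=["family", "k", "r2", "rmse"])
    metrics["r2_convention"] = config.flags["r2_convention"]
    metrics.to_csv(outdir / "cv_metrics.csv", index=False)
    pd.DataFrame(sel_rows, columns=["k", "fold", "feature"]).to_csv(
        outdir / "cv_selections.csv", index=False)
    return ins, [outdir / "cv_metrics.csv", outdir / "cv_selections.csv"]


def _stage_sweep(config: RunConfig, outdir: Path):
    ins = [outdir / "features.csv"]
    table = _load_assembled(config, outdir)
    folds = _folds_for(config, table)
    base = ModelSpec(family="random_forest",
                     n_features=config.k_features[0],
                     seed=config.seeds["model"])
    sweep = hyperparameter_sweep(table, folds,
                                 grid=config.hyperparameter_grid or None,
                                 base_spec=base)
    sweep["r2_convention"] = config.flags["r2_convention"]
    sweep.to_csv(outdir / "sweep_metrics.csv", index=False)
    return ins, [outdir / "sweep_metrics.csv"]


def _stage_ablate(config: RunConfig, outdir: Path):
    ins = [outdir / "features.csv", outdir / "annotation.csv"]
    table = _load_assembled(config, outdir)
    folds = _folds_for(config, table)
    annotation = kio.read_annotation(ins[1])
    k = config.k_features[0]
    configs = [
        {"classes": ("expression",), "k": k},
        {"classes": ("inhibition",), "k": k},
        {"classes": ("inhibition", "expression"), "k": k},
        {"classes": ("inhibition", "expression"), "k": k,
         "kinase_only": True},
    ]
    res = ablation_run(table, folds, configs, annotation=annotation)
    res.to_csv(outdir / "ablation_metrics.csv", index=False)
    return ins, [outdir / "ablation_metrics.csv"]


def _stage_enrich(config: RunConfig, outdir: Path):
    ins = [outdir / "features.csv", outdir / "network.tsv"]
    table = _load_assembled(config, outdir)
    graph = filter_network(build_network(kio.read_edge_list(ins[1])),
                           config.flags["min_confidence"])
    ranking = correlate_features(table)
    k = min(config.k_features[0], len(ranking))
    selected = rank_and_select(ranking, k,
                               signed=config.flags["signed_ranking"])
    query = [f[len("exp_"):] for f in selected if f.startswith("exp_")]
    universe = [f[len("exp_"):] for f in ranking["feature"]
                if f.startswith("exp_")]
    targets = [f[len("act_"):] for f in ranking["feature"]
               if f.startswith("act_")]
    if not query:
        raise PipelineError("no expression genes selected; nothing to enrich")
    result = resample_null(universe, targets, graph, query,
                           n_draws=10000, seed=config.seeds["resample"])
    payload = result.to_dict()
    payload["null_n_interacting"] = payload["null_n_interacting"][:0]
    payload["null_mean_interactors"] = payload["null_mean_interactors"][:0]
    payload["null_summary"] = {
        "n_mean": float(np.mean(result.null_n_interacting)),
        "n_sd": float(np.std(result.null_n_interacting)),
        "mean_mean": float(np.mean(result.null_mean_interactors)),
        "mean_sd": float(np.std(result.null_mean_interactors)),
    }
    (outdir / "enrichment.json").write_text(json.dumps(payload, indent=1))
    return ins, [outdir / "enrichment.json"]


def _stage_final(config: RunConfig, outdir: Path):
    ins = [outdir / "features.csv"]
    table = _load_assembled(config, outdir)
    k = config.k_features[0]
    spec = ModelSpec(family="random_forest", n_features=k,
                     seed=config.seeds["model"])
    final = fit_final_model(table, k=k, spec=spec,
                            include_dose=config.flags["include_dose"],
                            signed_ranking=config.flags["signed_ranking"])
    final.save(outdir / "final_model.pkl")
    (outdir / "final_selection.txt").write_text(
        "\n".join(final.selected_features) + "\n")
    return ins, [outdir / "final_model.pkl", outdir / "final_selection.txt"]


def _stage_predict(config: RunConfig, outdir: Path):
    from .predict import FinalModel
    ins = [outdir / "final_model.pkl", outdir / "clean_expression.csv",
           outdir / "profile.csv", outdir / "viability.csv"]
    final = FinalModel.load(ins[0])
    expression = kio.read_omics_matrix(ins[1])
    profile = kio.read_profile(outdir / "profile.csv")
    viab = kio.read_viability(ins[3])
    tested = set(zip(viab["cell_line"], viab["compound"]))
    grid_preds = predict_untested(final, expression, profile, tested)
    grid_preds.to_csv(outdir / "predictions.csv", index=False)
    return ins, [outdir / "predictions.csv"]


def _stage_validate(config: RunConfig, outdir: Path):
    ins = [outdir / "predictions.csv", outdir / "ground_truth.json",
           outdir / "viability.csv"]
    preds = pd.read_csv(ins[0])
    truth = GroundTruth.from_json(ins[1])
    measured = pd.DataFrame(
        [(l, j, x, v) for (l, j, x), v in truth.true_viability.items()],
        columns=["cell_line", "compound", "concentration", "viability"])
    mode = config.flags["r2_convention"]
    # replication check: imputed viability against the planted truth
    viab = kio.read_viability(ins[2])
    rep_r2, rep_rmse, rep_pairs = compare_validation(
        viab.rename(columns={"viability": "predicted"}), measured,
        r2_mode=mode)
    payload = {"replication": {"r2": rep_r2, "rmse": rep_rmse,
                               "n_pairs": len(rep_pairs)},
               "prediction": None,
               "r2_convention": mode}
    # prediction check: untested-combination predictions, when any exist
    if len(preds):
        r2, rmse, paired = compare_validation(preds, measured, r2_mode=mode)
        payload["prediction"] = {"r2": r2, "rmse": rmse,
                                 "n_pairs": len(paired)}
    (outdir / "validation.json").write_text(json.dumps(payload, indent=1))
    return ins, [outdir / "validation.json"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "impute": _stage_impute,
    "assemble": _stage_assemble,
    "cv": _stage_cv,
    "sweep": _stage_sweep,
    "ablate": _stage_ablate,
    "enrich": _stage_enrich,
    "final": _stage_final,
    "predict": _stage_predict,
    "validate": _stage_validate,
}


def pipeline_run(config: RunConfig, stages, outdir,
                 force: bool = False) -> dict[str, str]:
    """Run the requested stages in pipeline order.

    Returns a mapping stage -> "ran" | "skipped".  A stage whose
    dependencies have produced no outputs (neither in this call nor a
    previous one) raises PipelineError.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    stages = sorted(set(stages), key=STAGE_ORDER.index)
    status: dict[str, str] = {}
    for stage in stages:
        for dep in STAGE_DEPS[stage]:
            if dep in stages and stages.index(dep) < stages.index(stage):
                continue
            if not _manifest_path(outdir, dep).exists():
                raise PipelineError(
                    f"stage {stage!r} requested before its dependency "
                    f"{dep!r} has outputs")
    for stage in stages:
        fn = _STAGE_FUNCS[stage]
        if not force and _can_skip(outdir, stage, config):
            logger.info("stage %s skipped (up to date)", stage)
            status[stage] = "skipped"
            continue
        logger.info("running stage %s", stage)
        ins, outs = fn(config, outdir)
        _write_manifest(outdir, stage, config, ins, outs)
        status[stage] = "ran"
    return status
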