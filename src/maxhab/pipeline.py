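"""Config-driven orchestration of the full analysis.

``run_full`` executes: clean -> thin -> extract -> preliminary fit ->
collinearity pruning -> cross-validated fit -> evaluation -> per-scenario
projection (clamped) -> classification -> area/change/centroid accounting,
writing every product (CSV tables and ASCII grids) plus a manifest with
content hashes into the run directory.

One global seed fans out to stage-specific seeds through
``numpy.random.SeedSequence(seed).spawn``, in a fixed stage order
(background sample, fold partition, permutation importance), so each
stage is independently reproducible.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .habitat import classify, scenario_report
from .maxent import (
    MaxentParams,
    crossvalidate,
    classify_auc,
    jackknife,
    build_features,
    fit,
    percent_contribution,
    permutation_importance,
    predict_raster,
    sample_background,
    save_model,
)
from .occurrences import clean, read_occurrences_csv, thin, write_occurrences_csv
from .raster_io import Raster, assemble_stack, extract_at_points, read_ascii_grid, write_ascii_grid
from .variable_selection import pearson_matrix, prune

log = logging.getLogger("maxhab")

__all__ = ["PipelineConfig", "load_config", "run_full"]


@dataclass
class PipelineConfig:
    species: str
    occurrences: str
    scenarios: dict[str, str]  # name -> directory of .asc layers
    baseline: str
    output_dir: str
    seed: int = 0
    thinning_cellsize: float = 2.5 / 60
    thinning_anchor: tuple[float, float] | None = None  # default: grid ll corner
    correlation_threshold: float = 0.8
    correlation_scope: str = "background"  # or "occurrences"
    model: MaxentParams = field(default_factory=MaxentParams)
    breaks: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self):
        if self.baseline not in self.scenarios:
            raise ConfigError(
                f"baseline {self.baseline!r} not among scenarios {list(self.scenarios)}"
            )


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        model_cfg = dict(raw.get("model", {}))
        if "feature_classes" in model_cfg:
            model_cfg["feature_classes"] = tuple(model_cfg["feature_classes"])
        params = MaxentParams(seed=int(raw.get("seed", 0)), **model_cfg)
        thinning = raw.get("thinning", {})
        anchor = thinning.get("anchor")
        return PipelineConfig(
            species=raw["species"],
            occurrences=raw["occurrences"],
            scenarios=dict(raw["scenarios"]),
            baseline=raw["baseline"],
            output_dir=raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            thinning_cellsize=float(thinning.get("cellsize", 2.5 / 60)),
            thinning_anchor=tuple(anchor) if anchor else None,
            correlation_threshold=float(raw.get("selection", {}).get("threshold", 0.8)),
            correlation_scope=str(raw.get("selection", {}).get("scope", "background")),
            model=params,
            breaks=tuple(raw.get("classification", {}).get("breaks", (0.25, 0.5, 0.75))),
        )
    except KeyError as exc:
        raise ConfigError(f"config missing required key {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"invalid config entry: {exc}") from exc


def _load_scenario_stack(directory: str):
    paths = sorted(glob.glob(os.path.join(directory, "*.asc")))
    if not paths:
        raise DataError(f"no .asc layers found in {directory!r}")
    return assemble_stack([read_ascii_grid(p) for p in paths])


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _write_csv(df: pd.DataFrame, path: str):
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig) -> str:
    """Run the whole analysis; returns the run directory path."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    seed_background, seed_folds, seed_perm = seeds[0], seeds[1], seeds[2]
    stage = "setup"
    try:
        stage = "load_layers"
        stacks = {name: _load_scenario_stack(d) for name, d in config.scenarios.items()}
        base_stack = stacks[config.baseline]

        stage = "occurrences"
        raw = read_occurrences_csv(config.occurrences)
        cleaned = clean(raw, species=config.species, bounds=base_stack.spec)
        anchor = config.thinning_anchor or (
            base_stack.spec.xllcorner,
            base_stack.spec.yllcorner,
        )
        thinned = thin(cleaned, cellsize=config.thinning_cellsize, anchor=anchor)
        log.info(
            "occurrences: %d raw -> %d cleaned -> %d thinned",
            len(raw), len(cleaned), len(thinned),
        )
        write_occurrences_csv(thinned, os.path.join(out, "occurrences_thinned.csv"))
        _write_csv(
            pd.DataFrame([{**cleaned.provenance, "thinned": thinned.provenance["thinned"]}]),
            os.path.join(out, "occurrences_audit.csv"),
        )

        stage = "extract"
        coords = thinned.coords()
        pres_table = extract_at_points(base_stack, coords[:, 0], coords[:, 1])
        pres_table = pres_table[~pres_table["has_nodata"]].reset_index(drop=True)
        if len(pres_table) < 2:
            raise DataError("fewer than 2 presences with complete environmental data")

        stage = "background"
        bg_table = sample_background(base_stack, config.model.background_size, seed_background)
        var_names = base_stack.names

        stage = "variable_selection"
        params_prelim = MaxentParams(
            **{**_params_dict(config.model), "seed": seed_folds}
        )
        Fp, Fb, expansion = build_features(
            pres_table[var_names], bg_table, params_prelim
        )
        prelim = fit(Fp, Fb, expansion, params_prelim)
        contrib_prelim = percent_contribution(prelim)
        if config.correlation_scope == "occurrences":
            corr_table = pres_table[var_names]
        elif config.correlation_scope == "background":
            corr_table = bg_table[var_names]
        else:
            raise ConfigError(
                f"unknown correlation scope {config.correlation_scope!r}"
            )
        corr = pearson_matrix(corr_table)
        kept, drop_log = prune(corr, contrib_prelim, config.correlation_threshold)
        corr.to_frame().to_csv(os.path.join(out, "correlation_matrix.csv"))
        _write_csv(
            pd.DataFrame(drop_log, columns=["kept", "dropped", "r", "contribution_kept", "contribution_dropped"]),
            os.path.join(out, "variable_drop_log.csv"),
        )
        log.info("variable selection kept %d/%d variables", len(kept), len(var_names))

        stage = "crossvalidate"
        params = MaxentParams(**{**_params_dict(config.model), "seed": seed_folds})
        bg_kept = bg_table[["point_id", "lon", "lat"] + kept]
        models, evals, mean_raster = crossvalidate(
            pres_table[kept], bg_kept, params, stack=base_stack.subset(kept)
        )
        eval_df = evals.to_frame()
        _write_csv(eval_df, os.path.join(out, "evaluation.csv"))
        summary = {
            "mean_train_auc": evals.mean_train_auc,
            "mean_test_auc": evals.mean_test_auc,
            "sd_test_auc": evals.sd_test_auc,
            "auc_band": classify_auc(min(max(evals.mean_test_auc, 0.0), 1.0)),
        }

        stage = "importance"
        final = fit(*_features_for(pres_table, bg_kept, kept, params), params)
        save_model(final, os.path.join(out, "model_final.txt"))
        contrib = percent_contribution(final)
        perm = permutation_importance(final, pres_table[kept], bg_kept[kept], seed=seed_perm)
        jk = (
            jackknife(pres_table[kept], bg_kept[kept], params)
            if len(kept) >= 2
            else {"full_gain": final.gain, "variables": {}}
        )
        rows = []
        for v in kept:
            rows.append(
                {
                    "variable": v,
                    "percent_contribution": round(contrib[v], 1),
                    "permutation_importance": round(perm[v], 1),
                    "jackknife_gain_with_only": jk["variables"].get(v, {}).get("gain_with_only", float("nan")),
                    "jackknife_gain_without": jk["variables"].get(v, {}).get("gain_without", float("nan")),
                }
            )
        imp_df = pd.DataFrame(rows).sort_values(
            "percent_contribution", ascending=False, kind="mergesort"
        )
        _write_csv(imp_df, os.path.join(out, "importance_table.csv"))

        stage = "project"
        cmaps = {}
        for name in config.scenarios:
            sstack = stacks[name].subset(kept)
            if name == config.baseline:
                suit = mean_raster
            else:
                acc = None
                for model in models:
                    r = predict_raster(model, sstack)
                    acc = r.values if acc is None else acc + r.values
                suit = Raster(sstack.spec, acc / len(models), name="suitability_mean")
            write_ascii_grid(suit, os.path.join(out, f"suitability_{name}.asc"))
            cmaps[name] = classify(suit, breaks=config.breaks)
            write_ascii_grid(
                cmaps[name].to_raster(), os.path.join(out, f"classes_{name}.asc")
            )

        stage = "report"
        table, changes, track = scenario_report(config.baseline, cmaps)
        _write_csv(table, os.path.join(out, "area_table.csv"))
        for name, ch in changes.items():
            write_ascii_grid(ch.to_raster(), os.path.join(out, f"change_{name}.asc"))
        if track is not None:
            _write_csv(track.to_frame(), os.path.join(out, "centroid_track.csv"))

        stage = "manifest"
        outputs = sorted(
            p for p in glob.glob(os.path.join(out, "*")) if os.path.isfile(p)
            and os.path.basename(p) != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                "background": seed_background,
                "folds": seed_folds,
                "permutation": seed_perm,
            },
            "parameters": {
                "thinning_cellsize": config.thinning_cellsize,
                "correlation_threshold": config.correlation_threshold,
                "correlation_scope": config.correlation_scope,
                "breaks": list(config.breaks),
                "model": _params_dict(config.model),
            },
            "kept_variables": kept,
            "evaluation": summary,
            "files": {os.path.basename(p): _sha256(p) for p in outputs},
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out
    except Exception as exc:
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        try:
            with open(os.path.join(out, "error.json"), "w") as fh:
                json.dump(record, fh, indent=2)
        except OSError:
            pass
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _params_dict(params: MaxentParams) -> dict:
    return {
        "feature_classes": list(params.feature_classes),
        "beta_multiplier": params.beta_multiplier,
        "background_size": params.background_size,
        "max_iter": params.max_iter,
        "tol": params.tol,
        "transform": params.transform,
        "clamp": params.clamp,
        "replicates": params.replicates,
        "hinge_knots": params.hinge_knots,
    }


def _features_for(pres_table, bg_table, kept, params):
    Fp, Fb, expansion = build_features(pres_table[kept], bg_table[kept], params)
    return Fp, Fb, expansion
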