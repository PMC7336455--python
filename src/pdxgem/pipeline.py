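"""End-to-end pipeline runner: discover -> ccea -> train -> predict -> validate.

One YAML/dict config drives every stage; each stage also remains
independently runnable on intermediate files through the CLI subcommands.
All randomness funnels through a single root seed expanded deterministically
per stage, so a re-run with identical inputs reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__, dataio, evaluation, gem
from .model import PDXGem

__all__ = ["run_pipeline", "load_config", "PipelineStageError"]

log = logging.getLogger("pdxgem")

# fixed per-stage offsets applied to the root seed (kept below 2**31)
_SEED_OFFSETS = {"forest": 0, "bootstrap": 104729}


class PipelineStageError(RuntimeError):
    """A stage failed; completed artifacts are left on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s: start", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc
        log.info("stage %s: done", name)
        return out
    return wrap


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def run_pipeline(config, outdir) -> dict:
    """Execute the full pipeline from a config dict (or YAML path).

    Config keys::

        inputs:
          pdx_expr: pdx.tsv          # matrix_tsv (dialect: optional)
          activity: activity.csv
          patient_ref: cohort.tsv    # required unless ccea.skip
          validation:
            - {label: trial1, expr: val.tsv, outcome: outcome.csv}
        discovery: {method: auto, fdr: 0.05, nominal_fallback: true,
                    min_group_size: 2, correlation_flavor: spearman}
        ccea: {fdr: 0.05, min_ccec: 0.0, skip: false, correlation_flavor: pearson}
        gem: {trees: 500, seed: 17, importance: oob_permutation}
        evaluation: {responder_low: true, strata: median_split, n_boot: 2000}

    Writes ``biomarkers.csv``, ``ccea.csv``, ``model.joblib``,
    ``train_report.json``, per-cohort ``scores_<label>.csv`` and
    ``report_<label>.json``, and ``manifest.json``.  Returns the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = config.get("inputs", {})
    disc_cfg = config.get("discovery", {})
    ccea_cfg = config.get("ccea", {})
    gem_cfg = config.get("gem", {})
    eval_cfg = config.get("evaluation", {})
    root_seed = int(gem_cfg.get("seed", 0))
    skip_ccea = bool(ccea_cfg.get("skip", False))

    digests = {}

    def read_input(key, reader, path, **kwargs):
        digests[key] = _digest(path)
        return reader(path, **kwargs)

    pdx_expr = _stage("load")(
        read_input, "pdx_expr", dataio.read_expression, inputs["pdx_expr"],
        dialect=inputs.get("dialect", "matrix_tsv"),
    )
    activity = _stage("load")(read_input, "activity", dataio.read_activity,
                              inputs["activity"])
    reference = None
    if not skip_ccea:
        reference = _stage("load")(
            read_input, "patient_ref", dataio.read_expression,
            inputs["patient_ref"], dialect=inputs.get("dialect", "matrix_tsv"),
        )

    est = PDXGem(
        discovery_method=disc_cfg.get("method", "auto"),
        min_group_size=int(disc_cfg.get("min_group_size", 2)),
        discovery_fdr=float(disc_cfg.get("fdr", 0.05)),
        nominal_fallback=bool(disc_cfg.get("nominal_fallback", True)),
        discovery_selection=disc_cfg.get("selection", "fdr"),
        correlation_flavor=disc_cfg.get("correlation_flavor", "spearman"),
        ccea_flavor=ccea_cfg.get("correlation_flavor", "pearson"),
        ccea_fdr=float(ccea_cfg.get("fdr", 0.05)),
        min_ccec=float(ccea_cfg.get("min_ccec", 0.0)),
        skip_ccea=skip_ccea,
        n_trees=int(gem_cfg.get("trees", 500)),
        importance=gem_cfg.get("importance", "oob_permutation"),
        random_state=root_seed + _SEED_OFFSETS["forest"],
    )
    _stage("fit")(est.fit, pdx_expr, activity, reference=reference,
                  drug_label=str(config.get("drug_label", "")))

    est.biomarkers_.to_csv(outdir / "biomarkers.csv", index=False)
    if est.ccea_ is not None:
        est.ccea_.to_csv(outdir / "ccea.csv", index=False)
    gem.save_model(est.gem_, outdir / "model.joblib")
    train_report = {
        "stage_counts": est.stage_counts_,
        "training_r": est.training_r_,
        "training_r_oob": est.training_r_oob_,
        "n_trees": est.n_trees,
        "seed": root_seed,
        "alpha_mode": est.biomarkers_["alpha_mode"].iloc[0],
        "discovery_method": est.biomarkers_["method"].iloc[0],
    }
    (outdir / "train_report.json").write_text(
        json.dumps(_jsonable(train_report), indent=2))

    validations = {}
    for i, v in enumerate(inputs.get("validation", []) or []):
        label = str(v.get("label", f"cohort{i + 1}"))
        expr = _stage(f"predict:{label}")(
            read_input, f"validation:{label}:expr", dataio.read_expression,
            v["expr"], dialect=v.get("dialect", inputs.get("dialect", "matrix_tsv")),
        )
        scores = _stage(f"predict:{label}")(est.predict_scores, expr)
        scores.to_series().rename_axis("sample_id").reset_index().to_csv(
            outdir / f"scores_{label}.csv", index=False)
        if "outcome" in v and v["outcome"]:
            outcome = read_input(f"validation:{label}:outcome",
                                 dataio.read_outcome, v["outcome"])
            report = _stage(f"validate:{label}")(
                evaluation.validate, scores, outcome,
                cohort_label=label,
                responder_low=bool(eval_cfg.get("responder_low", True)),
                strata_mode=eval_cfg.get("strata", "median_split"),
                n_boot=int(eval_cfg.get("n_boot", 2000)),
                random_state=(root_seed + _SEED_OFFSETS["bootstrap"]) % (2 ** 31),
            )
            (outdir / f"report_{label}.json").write_text(
                json.dumps(_jsonable(report), indent=2))
            validations[label] = report

    manifest = {
        "pdxgem_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "input_digests": digests,
        "seeds": {"root": root_seed,
                  "forest": root_seed + _SEED_OFFSETS["forest"],
                  "bootstrap": (root_seed + _SEED_OFFSETS["bootstrap"]) % (2 ** 31)},
        "stages": {
            "discovery": {"n_features": int(len(est.biomarkers_)),
                          "n_selected": est.stage_counts_["discovered"],
                          "alpha_mode": est.biomarkers_["alpha_mode"].iloc[0]},
            "gem": {"n_features": est.stage_counts_["positive_importance"],
                    "training_r": est.training_r_,
                    "training_r_oob": est.training_r_oob_},
        },
        "stage_counts": est.stage_counts_,
        "validation": validations,
    }
    if est.ccea_ is not None:
        manifest["stages"]["ccea"] = {
            "n_candidates": int(len(est.ccea_)),
            "n_selected": est.stage_counts_["cce_selected"],
            "ccec_median": est.ccea_.attrs.get("ccec_median"),
        }
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
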