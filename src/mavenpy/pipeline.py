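"""End-to-end pipeline orchestration from a single YAML config.

Runs the stages in order — quantify (or load a precomputed matrix),
correlate, select, bootstrap, validate, render — into a run directory, and
writes a machine-readable manifest recording every stage's parameters,
seeds and input-file hashes.  Rerunning with the same config reproduces all
outputs bit-exactly (the manifest's wall-clock timestamp is the only
field that differs).

Config layout (every key optional unless marked)::

    input:
      matrix: matrix.csv          # either a precomputed matrix ...
      stacks_dir: stacks/         # ... or a directory of <subject_id>.tif
      atlas_labels: labels.tif    # label volume or mask directory
      atlas_regions: regions.tsv
      subjects: subjects.csv      # required
    quantify: {norm: per_brain_mean, statistic: mean, min_variance: 0.0}
    correlate: {focal: region_017, k: 10, containment_threshold: 0.99}
    select: {n_folds: 5, rule: one_se, seed: 0, exclude: []}
    bootstrap: {n_models: 100, train_fraction: 0.5, seed: 0}
    validate: {region: region_017}   # defaults to the model's top region
    render: {k: 10}
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import collinearity, core_io, quantify, select, validate_stats, viz
from .errors import PipelineStageError, ValidationError

__all__ = ["run_pipeline", "load_config"]

STAGES = ("quantify", "correlate", "select", "bootstrap", "validate", "render")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "input" not in cfg:
        raise ValidationError("config must be a mapping with an 'input' section")
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_pipeline(config_path, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises :class:`PipelineStageError` naming the stage.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": [], "input_hashes": {}, "timestamp": time.time()}

    inp = cfg["input"]
    base = Path(config_path).parent

    def _p(key):
        return (base / inp[key]).resolve() if key in inp else None

    for key in ("matrix", "subjects", "atlas_labels", "atlas_regions"):
        path = _p(key)
        if path is not None and path.is_file():
            manifest["input_hashes"][key] = _hash_file(path)

    try:
        subjects = core_io.read_subjects(_p("subjects"))
    except Exception as exc:
        raise PipelineStageError("quantify", exc) from exc

    # --- stage 1: quantify (or load) --------------------------------------
    stage_cfg = cfg.get("quantify", {}) or {}
    try:
        atlas = None
        if _p("atlas_labels") is not None:
            atlas = core_io.read_atlas(_p("atlas_labels"), _p("atlas_regions"))
        if _p("matrix") is not None:
            m = core_io.read_signal_matrix(_p("matrix"))
            source = "loaded"
        else:
            if atlas is None:
                raise ValidationError("need either input.matrix or stacks + atlas")
            stacks_dir = _p("stacks_dir")
            stacks = [
                core_io.BrainStack.from_file(f.stem, f)
                for f in sorted(stacks_dir.glob("*.tif"))
            ]
            norm = quantify.NormalizationSpec(
                method=stage_cfg.get("norm", "per_brain_mean"),
                statistic=stage_cfg.get("statistic", "mean"),
            )
            m = quantify.build_signal_matrix(stacks, atlas, norm)
            source = "quantified"
        m, dropped = quantify.drop_uninformative_regions(
            m, float(stage_cfg.get("min_variance", 0.0))
        )
        core_io.write_signal_matrix(m, out / "matrix.csv")
        manifest["stages"].append(
            {"stage": "quantify", "source": source, "dropped_regions": dropped,
             "n_subjects": m.shape[0], "n_regions": m.shape[1],
             "normalization": m.normalization_tag}
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("quantify", exc) from exc

    # --- stage 2: correlate ------------------------------------------------
    stage_cfg = cfg.get("correlate", {}) or {}
    try:
        report = collinearity.correlation_matrix(m)
        focal = stage_cfg.get("focal")
        ranking = None
        if focal is not None:
            ranking = collinearity.strongest_correlated_regions(
                report, focal, int(stage_cfg.get("k", 10)), atlas,
                float(stage_cfg.get("containment_threshold", 0.99)),
            )
        _json_dump(
            {
                "region_ids": report.region_ids,
                "r": np.round(report.r, 12).tolist(),
                "ordering": report.ordering.tolist(),
                "linkage_method": report.linkage_method,
                "dissimilarity": report.dissimilarity,
                "focal": focal,
                "ranking": ranking,
            },
            out / "correlation.json",
        )
        manifest["stages"].append({"stage": "correlate", "focal": focal,
                                   "k": stage_cfg.get("k", 10)})
    except Exception as exc:
        raise PipelineStageError("correlate", exc) from exc

    # --- stage 3: select ---------------------------------------------------
    stage_cfg = cfg.get("select", {}) or {}
    try:
        seed = int(stage_cfg.get("seed", 0))
        exclude = list(stage_cfg.get("exclude", []) or [])
        m_sel = m.drop_regions(exclude) if exclude else m
        cv = select.select_lambda_cv(
            m_sel, subjects, n_folds=int(stage_cfg.get("n_folds", 5)),
            rule=stage_cfg.get("rule", "one_se"), seed=seed, full_output=True,
        )
        model = select.fit_lasso(m_sel, subjects, cv.lam)
        model_dict = model.to_dict()
        model_dict["provenance"] = {
            "seed": seed, "rule": cv.rule, "n_folds": cv.n_folds,
            "lambda_grid": cv.grid.tolist(), "excluded_regions": exclude,
            "normalization": m.normalization_tag,
            "selected_regions": model.selected_regions,
            "top_region": model.top_region,
            "train_accuracy": select.accuracy(model, m_sel, subjects),
        }
        _json_dump(model_dict, out / "model.json")
        manifest["stages"].append(
            {"stage": "select", "lambda": cv.lam, "seed": seed,
             "selected_regions": model.selected_regions, "top_region": model.top_region}
        )
    except Exception as exc:
        raise PipelineStageError("select", exc) from exc

    # --- stage 4: bootstrap -----------------------------------------------
    stage_cfg = cfg.get("bootstrap", {}) or {}
    try:
        boot = select.bootstrap_lasso(
            m, subjects,
            n_models=int(stage_cfg.get("n_models", 100)),
            train_fraction=float(stage_cfg.get("train_fraction", 0.5)),
            seed=int(stage_cfg.get("seed", 0)),
            n_folds=int(stage_cfg.get("n_folds", 5)),
            rule=stage_cfg.get("rule", "one_se"),
        )
        boot.to_json(out / "bootstrap.json")
        near = np.abs(boot.test_accuracy - 0.5) * len(m.subjects) // 2 < 1
        manifest["stages"].append(
            {"stage": "bootstrap", "n_models": boot.n_models,
             "n_accurate": boot.n_accurate, "seed": boot.rng_seed,
             "near_boundary_models": int(near.sum())}
        )
    except Exception as exc:
        raise PipelineStageError("bootstrap", exc) from exc

    # --- stage 5: validate -------------------------------------------------
    stage_cfg = cfg.get("validate", {}) or {}
    try:
        region = stage_cfg.get("region") or model.top_region or m.regions[0]
        signal = m.column(region)
        yy = subjects.aligned_to(m)
        # two-factor ANOVA needs >= 2 genotype classes; a single-genotype
        # sorting experiment falls back to the rank test alone
        if len(np.unique(yy.genotype)) >= 2:
            anova = validate_stats.two_way_anova(signal, yy.phenotype, yy.genotype)
            anova_payload = {
                "effects": {
                    name: {"ss": e.ss, "df": e.df, "F": e.F, "p": e.p}
                    for name, e in anova.effects.items()
                },
                "posthoc": anova.posthoc,
            }
            anova_p = anova.p("phenotype")
        else:
            anova_payload = None
            anova_p = None
        groups = [signal[yy.phenotype == c] for c in (0, 1)]
        U, p_mwu = validate_stats.mann_whitney_u(groups[0], groups[1])
        _json_dump(
            {
                "region": region,
                "anova": anova_payload,
                "mann_whitney": {"U": U, "p": p_mwu},
            },
            out / "stats.json",
        )
        manifest["stages"].append(
            {"stage": "validate", "region": region,
             "anova_phenotype_p": anova_p, "mwu_p": p_mwu}
        )
    except Exception as exc:
        raise PipelineStageError("validate", exc) from exc

    # --- stage 6: render ---------------------------------------------------
    stage_cfg = cfg.get("render", {}) or {}
    try:
        if atlas is not None:
            focal = model.top_region or m.regions[0]
            present = [r for r in m.regions if r in set(atlas.region_ids)]
            rep = collinearity.correlation_matrix(m.subset_regions(present))
            ranking = collinearity.strongest_correlated_regions(
                rep, focal, int(stage_cfg.get("k", 10)), atlas
            )
            smap = viz.RegionScoreMap(scores=dict(ranking), focal=focal)
            stack, proj = viz.render_region_stack(atlas, smap)
            viz.save_render(stack, proj, out / "render_stack.tif", out / "render_projection.png")
            manifest["stages"].append(
                {"stage": "render", "focal": focal, "n_scored": len(ranking)}
            )
        else:
            manifest["stages"].append(
                {"stage": "render", "skipped": "no atlas in config"}
            )
    except Exception as exc:
        raise PipelineStageError("render", exc) from exc

    _json_dump(manifest, out / "manifest.json")
    return out
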