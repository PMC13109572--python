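"""Stage-based pipeline: simulate -> fuse -> indices -> label -> train ->
predict -> profile -> stats.

Every stage reads its inputs from and writes its outputs to one run
directory, records a ``<stage>.manifest.json`` (resolved config hash, input
file hashes, package version, wall time), and derives its own seed from the
single run seed, so a re-run with unchanged inputs reproduces byte-identical
tabular outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
import zlib
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cloud import PointCloud
from .errors import ConfigurationError, PipelineError
from .fpar import (PAPER_THRESHOLDS, StratumThresholds, assign_strata,
                   derive_thresholds, label_voxels, layer_fpar_table)
from .fusion import propagate_reflectance, voxelize
from .indices import INDEX_NAMES, compute_all
from .lidar import (HeightRaster, TreeSegmentation, classify_ground,
                    normalize_heights, rasterize_chm, read_las, segment_trees,
                    write_las)
from .models import (ModelSpec, permutation_importance, predict_voxels,
                     split_data, train_model, validate_model)
from .raster import MultiBandRaster, read_single_band, write_single_band
from .stats import aggregate, duncan_mrt, one_way_anova, vertical_profile
from .synthetic import (StandConfig, generate_stand, render_orthomosaic,
                        sample_point_cloud, save_scene, simulate_par)

STAGES = ("simulate", "fuse", "indices", "label", "train", "predict",
          "profile", "stats")

#: artifact -> stage that produces it (for actionable missing-input errors)
_PRODUCERS = {
    "scene.yaml": "simulate", "points.las": "simulate", "ortho.tif": "simulate",
    "par.csv": "simulate", "stems.csv": "simulate",
    "chm.tif": "fuse", "labels.tif": "fuse", "trees.csv": "fuse",
    "fused.csv": "fuse",
    "indexed.csv": "indices",
    "labeled.csv": "label", "training.csv": "label", "tree_fpar.csv": "label",
    "model.joblib": "train", "metrics.yaml": "train",
    "predictions.csv": "predict",
    "profile.csv": "profile",
}

DEFAULT_CONFIG = {
    "seed": 0,
    "stand": {"n_rows": 6, "n_cols": 8},
    "simulate": {
        "point_density": 40.0, "lidar_noise_sd": 0.05, "ortho_gsd": 0.10,
        "incident_par": 1800.0, "sensor_heights": [20.0, 10.0, 4.0],
        "date": "2023-07-15",
    },
    "lidar": {
        "ground_cell": 2.0, "ground_tolerance": 0.2, "chm_gsd": 0.25,
        "smooth_sigma": 1.0, "min_height": 2.0, "min_distance": 3,
    },
    "fusion": {"dx": 0.25, "dy": 0.25, "dz": 2.0},
    "indices": {"variant": "canonical"},
    "label": {
        "thresholds_mode": "fixed", "t_upper": 15.0, "t_lower": 7.0,
        "p_upper": 75.0, "p_lower": 40.0, "fpar_mode": "paper",
        "tau_floor": 0.0,
    },
    "model": {
        "algorithm": "RF", "grid_search": False, "split_fraction": 0.8,
        "cv_folds": 10, "cv_repeats": 5, "importance_repeats": 10,
    },
    "stats": {"profile_bin": 5.0, "alpha": 0.05},
}


def resolve_config(overrides: dict | None = None,
                   seed: int | None = None) -> dict:
    """Deep-merge user overrides onto the defaults."""
    def merge(base, extra):
        out = copy.deepcopy(base)
        for key, val in (extra or {}).items():
            if isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = merge(out[key], val)
            else:
                out[key] = copy.deepcopy(val)
        return out

    config = merge(DEFAULT_CONFIG, overrides or {})
    if seed is not None:
        config["seed"] = int(seed)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    return config


def load_config(path, seed: int | None = None) -> dict:
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return resolve_config(overrides, seed=seed)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _require(outdir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            producer = _PRODUCERS.get(name, "an earlier stage")
            raise PipelineError(
                f"missing artifact {name!r}; run the {producer!r} stage first")
        paths.append(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: dict,
                    inputs: list[Path], wall_time: float) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config["seed"],
        "stage_seed": stage_seed(config["seed"], stage),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest(),
        "input_sha256": {p.name: _sha256(p) for p in inputs},
        "wall_time_s": round(wall_time, 3),
    }
    with open(outdir / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_stage(stage: str, config: dict, outdir) -> dict:
    """Execute one pipeline stage; returns a summary dict."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; one of {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    fn = globals()[f"_stage_{stage}"]
    inputs, summary = fn(config, outdir)
    _write_manifest(outdir, stage, config, inputs, time.perf_counter() - t0)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return summary


def run_all(config: dict, outdir) -> dict:
    summary = {}
    for stage in STAGES:
        summary[stage] = run_stage(stage, config, outdir)
    return summary


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config, outdir):
    seed = stage_seed(config["seed"], "simulate")
    sim = config["simulate"]
    stand_kwargs = dict(config["stand"])
    stand_kwargs["seed"] = seed
    scene = generate_stand(StandConfig(**stand_kwargs))
    cloud = sample_point_cloud(scene, point_density=sim["point_density"],
                               noise_sd=sim["lidar_noise_sd"], seed=seed + 1)
    ortho = render_orthomosaic(scene, gsd=sim["ortho_gsd"])
    par = simulate_par(scene, incident_par=sim["incident_par"],
                       sensor_heights=tuple(sim["sensor_heights"]),
                       seed=seed + 2, date=sim["date"])
    save_scene(scene, outdir / "scene.yaml")
    write_las(cloud, outdir / "points.las")
    ortho.to_tiff(outdir / "ortho.tif")
    _csv(par, outdir / "par.csv")
    _csv(scene.trees[["tree_id", "family_id", "x", "y", "height"]],
         outdir / "stems.csv")
    return [], {"n_trees": scene.n_trees, "n_points": len(cloud)}


def _stage_fuse(config, outdir):
    inputs = _require(outdir, "points.las", "ortho.tif")
    lid = config["lidar"]
    fus = config["fusion"]
    cloud = read_las(outdir / "points.las")
    ortho = MultiBandRaster.from_tiff(outdir / "ortho.tif")
    classified = classify_ground(cloud, cell=lid["ground_cell"],
                                 tolerance=lid["ground_tolerance"])
    normalized = normalize_heights(classified, cell=lid["ground_cell"])
    chm = rasterize_chm(normalized, gsd=lid["chm_gsd"])
    seg = segment_trees(chm, smooth_sigma=lid["smooth_sigma"],
                        min_height=lid["min_height"],
                        min_distance=lid["min_distance"])
    canopy = normalized.subset(~normalized.is_ground)
    grid = voxelize(canopy, dx=fus["dx"], dy=fus["dy"], dz=fus["dz"])
    fused = propagate_reflectance(grid, ortho)
    write_single_band(outdir / "chm.tif", chm.values.astype(np.float32),
                      chm.origin_x, chm.origin_y, chm.cell)
    write_single_band(outdir / "labels.tif", seg.labels.astype(np.int32),
                      chm.origin_x, chm.origin_y, chm.cell)
    _csv(seg.trees, outdir / "trees.csv")
    _csv(fused, outdir / "fused.csv")
    return inputs, {"n_trees_segmented": seg.n_trees, "n_voxels": len(fused)}


def _stage_indices(config, outdir):
    inputs = _require(outdir, "fused.csv")
    fused = pd.read_csv(outdir / "fused.csv")
    indexed = compute_all(fused, variant=config["indices"]["variant"])
    _csv(indexed, outdir / "indexed.csv")
    return inputs, {"variant": config["indices"]["variant"],
                    "n_voxels": len(indexed)}


def _load_segmentation(outdir) -> TreeSegmentation:
    labels, x0, y0, cell = read_single_band(outdir / "labels.tif")
    chm_vals, *_ = read_single_band(outdir / "chm.tif")
    raster = HeightRaster(x0, y0, cell, chm_vals)
    trees = pd.read_csv(outdir / "trees.csv")
    return TreeSegmentation(labels.astype(int), raster, trees)


def _relabel_segments(seg: TreeSegmentation,
                      stems: pd.DataFrame) -> TreeSegmentation:
    """Remap watershed segment ids to surveyed stem (tree) ids.

    Each measured stem claims the segment containing its (x, y); segments
    without a stem become background, duplicate claims keep the first stem.
    """
    seg_ids = seg.label_at(stems["x"].to_numpy(), stems["y"].to_numpy())
    remap = {}
    for stem_id, sid in zip(stems["tree_id"], seg_ids):
        if sid == 0:
            warnings.warn(f"stem {stem_id} falls outside every segment")
        elif sid in remap:
            warnings.warn(f"stems {remap[sid]} and {stem_id} share segment "
                          f"{sid}; keeping the first")
        else:
            remap[sid] = int(stem_id)
    lookup = np.zeros(seg.labels.max() + 1, dtype=int)
    for sid, stem_id in remap.items():
        lookup[sid] = stem_id
    new_labels = lookup[seg.labels]
    trees = seg.trees[seg.trees["tree_id"].isin(remap)].copy()
    trees["tree_id"] = trees["tree_id"].map(remap)
    return TreeSegmentation(new_labels, seg.raster,
                            trees.reset_index(drop=True))


def _stage_label(config, outdir):
    inputs = _require(outdir, "indexed.csv", "par.csv", "stems.csv",
                      "labels.tif", "chm.tif", "trees.csv")
    lab = config["label"]
    indexed = pd.read_csv(outdir / "indexed.csv")
    par = pd.read_csv(outdir / "par.csv")
    stems = pd.read_csv(outdir / "stems.csv")
    seg = _relabel_segments(_load_segmentation(outdir), stems)

    if lab["thresholds_mode"] == "fixed":
        thresholds = StratumThresholds(lab["t_upper"], lab["t_lower"])
    elif lab["thresholds_mode"] == "percentile":
        seg_heights = pd.read_csv(outdir / "trees.csv")["apex_height"]
        thresholds = derive_thresholds(seg_heights, lab["p_upper"],
                                       lab["p_lower"])
    else:
        raise ConfigurationError(
            f"thresholds_mode must be fixed|percentile, got "
            f"{lab['thresholds_mode']!r}")

    stratified = assign_strata(indexed, thresholds)
    strata_fpar = layer_fpar_table(par, tau_floor=lab["tau_floor"])
    labeled, training = label_voxels(stratified, strata_fpar, seg)
    _csv(labeled, outdir / "labeled.csv")
    _csv(training, outdir / "training.csv")
    _csv(strata_fpar, outdir / "tree_fpar.csv")
    return inputs, {"thresholds": [thresholds.t_upper, thresholds.t_lower],
                    "n_labeled": int(labeled["fpar_label"].notna().sum()),
                    "n_training_rows": len(training)}


def _stage_train(config, outdir):
    inputs = _require(outdir, "training.csv")
    mod = config["model"]
    seed = stage_seed(config["seed"], "train")
    training = pd.read_csv(outdir / "training.csv")
    spec = ModelSpec(algorithm=mod["algorithm"], seed=seed)
    calibration, validation = split_data(training, mod["split_fraction"],
                                         seed=seed)
    fit = train_model(calibration, spec, n_splits=mod["cv_folds"],
                      n_repeats=mod["cv_repeats"],
                      grid_search=mod["grid_search"])
    val_r2, val_rmse = validate_model(fit, validation)
    importance = permutation_importance(fit, validation,
                                        n_repeats=mod["importance_repeats"],
                                        seed=seed)
    joblib.dump(fit, outdir / "model.joblib")
    metrics = {
        "algorithm": spec.algorithm, "seed": seed,
        "best_params": fit.best_params,
        "calibration_r2": round(fit.calibration_r2, 6),
        "calibration_rmse": round(fit.calibration_rmse, 6),
        "cv_r2_mean": round(fit.cv_r2_mean, 6),
        "cv_rmse_mean": round(fit.cv_rmse_mean, 6),
        "validation_r2": round(float(val_r2), 6),
        "validation_rmse": round(float(val_rmse), 6),
        "n_calibration_rows": fit.n_rows,
        "n_validation_rows": int(validation[fit.target].notna().sum()),
    }
    with open(outdir / "metrics.yaml", "w") as fh:
        yaml.safe_dump(metrics, fh, sort_keys=True)
    _csv(fit.cv_results, outdir / "cv_results.csv")
    _csv(importance, outdir / "importance.csv")
    return inputs, metrics


def _stage_predict(config, outdir):
    inputs = _require(outdir, "labeled.csv", "model.joblib")
    labeled = pd.read_csv(outdir / "labeled.csv")
    fit = joblib.load(outdir / "model.joblib")
    predictions = predict_voxels(fit, labeled)
    _csv(predictions, outdir / "predictions.csv")
    return inputs, {"n_predicted": int(predictions["fpar_pred"].notna().sum()),
                    "n_clipped": int(predictions["pred_clipped"].sum())}


def _stage_profile(config, outdir):
    inputs = _require(outdir, "predictions.csv")
    predictions = pd.read_csv(outdir / "predictions.csv")
    profile = vertical_profile(predictions,
                               bin_width=config["stats"]["profile_bin"])
    _csv(profile, outdir / "profile.csv")
    return inputs, {"n_bins": len(profile)}


def _stage_stats(config, outdir):
    inputs = _require(outdir, "predictions.csv", "stems.csv")
    alpha = config["stats"]["alpha"]
    predictions = pd.read_csv(outdir / "predictions.csv")
    stems = pd.read_csv(outdir / "stems.csv")
    trees = predictions[predictions["tree_id"] > 0]

    # per-tree stratum means -> layer effect
    layer_means = aggregate(trees, by=["tree_id", "stratum"])
    layer_groups = [g["mean"].to_numpy()
                    for _, g in layer_means.groupby("stratum")]
    layer_labels = [name for name, _ in layer_means.groupby("stratum")]
    anova_rows = []
    duncan_frames = []
    if len(layer_groups) >= 2:
        res = one_way_anova(layer_groups)
        anova_rows.append(("layer", res.f, res.df1, res.df2, res.p))
        letters = duncan_mrt(layer_groups, alpha=alpha, labels=layer_labels,
                             anova=res)
        letters.insert(0, "factor", "layer")
        duncan_frames.append(letters)

    # whole-tree means -> family effect
    tree_means = aggregate(trees, by=["tree_id"])
    tree_means = tree_means.merge(stems[["tree_id", "family_id"]], on="tree_id")
    fam_groups = [g["mean"].to_numpy()
                  for _, g in tree_means.groupby("family_id") if len(g) >= 1]
    fam_labels = [str(name) for name, g in tree_means.groupby("family_id")
                  if len(g) >= 1]
    if len(fam_groups) >= 2 and sum(len(g) for g in fam_groups) > len(fam_groups):
        res = one_way_anova(fam_groups)
        anova_rows.append(("family", res.f, res.df1, res.df2, res.p))
        letters = duncan_mrt(fam_groups, alpha=alpha, labels=fam_labels,
                             anova=res)
        letters.insert(0, "factor", "family")
        duncan_frames.append(letters)

    anova = pd.DataFrame(anova_rows, columns=["factor", "F", "df1", "df2", "p"])
    _csv(anova, outdir / "anova.csv")
    if duncan_frames:
        _csv(pd.concat(duncan_frames, ignore_index=True),
             outdir / "duncan.csv")
    _csv(layer_means, outdir / "layer_means.csv")
    _csv(tree_means, outdir / "tree_means.csv")
    return inputs, {"anova": anova.to_dict(orient="records")}
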