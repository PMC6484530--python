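"""Pipeline orchestration: simulate → stitch → segment → analyze → profile.

Driven by a single YAML config with a master seed.  Stages are pure
file-to-file; each stage writes a hash of its config subsection so
re-running skips completed stages whose inputs are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging_io, junctions, morphometry, notch, profiling, synthgen
from .imaging_io import FieldImage, read_field, write_field
from .junctions import JunctionParams
from .notch import SpotParams
from .segmentation import LabelMask, SegParams, segment_cells, segment_nuclei
from .synthgen import DEFAULT_LAYOUT, ExperimentLayout, SceneParams

__all__ = ["ConfigError", "load_config", "run_pipeline", "analyze_area",
           "default_config"]

log = logging.getLogger(__name__)

_ALLOWED = {
    "seed": None,
    "out_dir": None,
    "simulate": {"cell_models", "treatments", "replicates_per_condition",
                 "areas_per_replicate", "tile_grid", "tile_overlap_frac",
                 "tile_size", "scene"},
    "input": {"manifest"},
    "segment": {f.name for f in dataclasses.fields(SegParams)},
    "junctions": {f.name for f in dataclasses.fields(JunctionParams)},
    "notch": {f.name for f in dataclasses.fields(SpotParams)},
    "features": {"registry"},
    "profile": {"components", "linkage"},
}
_SCENE_KEYS = {f.name for f in dataclasses.fields(SceneParams)}


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "ecprof_out",
        "simulate": {
            "cell_models": list(DEFAULT_LAYOUT.cell_models),
            "treatments": list(DEFAULT_LAYOUT.treatments),
            "replicates_per_condition":
                DEFAULT_LAYOUT.replicates_per_condition,
            "areas_per_replicate": DEFAULT_LAYOUT.areas_per_replicate,
            "tile_grid": list(DEFAULT_LAYOUT.tile_grid),
            "tile_overlap_frac": DEFAULT_LAYOUT.tile_overlap_frac,
            "tile_size": list(DEFAULT_LAYOUT.tile_size),
            "scene": {},
        },
        "segment": {}, "junctions": {}, "notch": {},
        "features": {}, "profile": {"components": 3, "linkage": "average"},
    }


def validate_config(cfg: dict) -> None:
    bad = [k for k in cfg if k not in _ALLOWED]
    for sect, allowed in _ALLOWED.items():
        if allowed is None or sect not in cfg:
            continue
        sub = cfg[sect]
        if not isinstance(sub, dict):
            raise ConfigError(f"section {sect!r} must be a mapping")
        bad += [f"{sect}.{k}" for k in sub if k not in allowed]
        if sect == "simulate" and "scene" in sub:
            bad += [f"simulate.scene.{k}" for k in sub["scene"]
                    if k not in _SCENE_KEYS]
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    validate_config(user)
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _layout_from_config(cfg: dict) -> ExperimentLayout:
    s = cfg["simulate"]
    return ExperimentLayout(
        cell_models=tuple(s["cell_models"]),
        treatments=tuple(s["treatments"]),
        replicates_per_condition=s["replicates_per_condition"],
        areas_per_replicate=s["areas_per_replicate"],
        tile_grid=tuple(s["tile_grid"]),
        tile_overlap_frac=s["tile_overlap_frac"],
        tile_size=tuple(s["tile_size"]))


def _base_scene(cfg: dict) -> SceneParams:
    over = dict(cfg["simulate"].get("scene", {}))
    for key in ("frame_size", "category_probs"):
        if key in over:
            over[key] = tuple(over[key])
    return SceneParams(**over)


def _stage_hash(cfg_subset) -> str:
    return hashlib.sha256(
        json.dumps(cfg_subset, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_done(stamp: Path, h: str) -> bool:
    return stamp.exists() and stamp.read_text() == h


def analyze_area(field: FieldImage,
                 seg_params: SegParams | None = None,
                 junc_params: JunctionParams | None = None,
                 spot_params: SpotParams | None = None,
                 annotations: dict | None = None,
                 area_name: str = "area",
                 ) -> tuple[pd.DataFrame, dict, dict]:
    """Run segmentation → junctions → NOTCH → morphometry on one area.

    Returns (cell table, area feature row, intermediate objects).  This is
    the in-memory core used by the file-based ``run_pipeline`` stages and by
    the validation suites.
    """
    seg_params = seg_params or SegParams()
    junc_params = junc_params or JunctionParams()
    spot_params = spot_params or SpotParams()

    nuclei = segment_nuclei(field, seg_params)
    cells = segment_cells(field, nuclei, seg_params)

    jchan = field.channel("junction").astype(float)
    ridge = junctions.junction_enhance(jchan, junc_params)
    jset = junctions.detect_junctions(ridge, cells, nuclei, junc_params,
                                      intensity=jchan)
    spots = notch.detect_spots(field.channel("spots"), spot_params)
    notch_res, spots = notch.classify_notch(spots, nuclei, cells)
    graph = notch.cell_adjacency(cells, seg_params.min_shared_border)
    clusters = notch.notch_clusters(graph, notch_res.categories)

    channels = {r: field.channel(r).astype(float)
                for r in ("nuclear", "junction", "spots")}
    table = morphometry.build_cell_table(cells, nuclei, channels, jset,
                                         notch_res, clusters,
                                         area_name=area_name)
    if table.empty:
        raise ValueError(f"no cells in area {area_name}")
    row = profiling.aggregate_area(table, jset=jset, notch=notch_res,
                                   clusters=clusters,
                                   annotations=annotations)
    inter = {"nuclei": nuclei, "cells": cells, "jset": jset,
             "spots": spots, "notch": notch_res, "graph": graph,
             "clusters": clusters}
    return table, row, inter


def run_pipeline(config_path, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full pipeline from a YAML config; returns the manifest.

    Outputs under ``out_dir``: simulated tiles + ground truth, stitched
    mosaics, masks, per-area cell tables, ``features.csv`` and
    ``profile.json``.  Stages whose config hash and outputs already exist
    are skipped.
    """
    cfg = load_config(config_path)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline start: out=%s seed=%s", out, cfg["seed"])

    # --- simulate ---------------------------------------------------------
    sim_dir = out / "simulated"
    sim_hash = _stage_hash([cfg["simulate"], cfg["seed"]])
    stamp = sim_dir / ".stage_hash"
    if _stage_done(stamp, sim_hash) and (sim_dir / "manifest.json").exists():
        log.info("simulate: up to date, skipping")
        manifest = json.loads((sim_dir / "manifest.json").read_text())
    else:
        layout = _layout_from_config(cfg)
        manifest = synthgen.generate_experiment(layout, cfg["seed"], sim_dir,
                                                base_params=_base_scene(cfg))
        stamp.write_text(sim_hash)

    # --- stitch -----------------------------------------------------------
    mos_dir = out / "mosaics"
    mos_dir.mkdir(exist_ok=True)
    st_hash = _stage_hash([sim_hash])
    st_stamp = mos_dir / ".stage_hash"
    redo_stitch = not _stage_done(st_stamp, st_hash)
    for area in manifest["areas"]:
        mpath = mos_dir / f"{area['name']}.tif"
        if redo_stitch or not mpath.exists():
            grid = tuple(area["tile_grid"])
            tiles = [read_field(sim_dir / t["path"])
                     for t in sorted(area["tiles"],
                                     key=lambda t: (t["row"], t["col"]))]
            mosaic = imaging_io.stitch_area(tiles, grid,
                                            area["tile_overlap_frac"])
            write_field(mosaic, mpath)
        area["mosaic"] = str(mpath.relative_to(out))
    st_stamp.write_text(st_hash)

    # --- segment + analyze ------------------------------------------------
    seg_params = SegParams(**cfg["segment"])
    junc_params = JunctionParams(**cfg["junctions"])
    spot_params = SpotParams(**cfg["notch"])
    an_dir = out / "analysis"
    an_dir.mkdir(exist_ok=True)
    an_hash = _stage_hash([st_hash, cfg["segment"], cfg["junctions"],
                           cfg["notch"]])
    an_stamp = an_dir / ".stage_hash"
    redo_an = not _stage_done(an_stamp, an_hash)
    rows = []
    for area in manifest["areas"]:
        tpath = an_dir / f"{area['name']}_cells.csv"
        rpath = an_dir / f"{area['name']}_row.json"
        if redo_an or not (tpath.exists() and rpath.exists()):
            field = read_field(out / area["mosaic"])
            ann = {"area_id": area["name"],
                   "cell_model": area["cell_model"],
                   "treatment": area["treatment"],
                   "replicate": area["replicate"], "area": area["area"]}
            table, row, inter = analyze_area(
                field, seg_params, junc_params, spot_params,
                annotations=ann, area_name=area["name"])
            table.to_csv(tpath, index=False)
            rpath.write_text(json.dumps(row))
            for kind in ("nuclei", "cells"):
                mask: LabelMask = inter[kind]
                imaging_io.tifffile.imwrite(
                    an_dir / f"{area['name']}_{kind}.tif",
                    mask.labels.astype(np.uint16))
        else:
            row = json.loads(rpath.read_text())
        area["cell_table"] = str(tpath.relative_to(out))
        rows.append(row)
    an_stamp.write_text(an_hash)

    # --- profile ----------------------------------------------------------
    table = profiling.profile_table(rows)
    table.to_csv(out / "features.csv", index=False)
    if len(table) >= 2:
        norm = profiling.normalize_features(table)
        k = min(cfg["profile"]["components"],
                len(table) - 1, morphometry.N_FEATURES)
        res = profiling.pca_profile(norm, k=k)
        res = profiling.hcluster(norm, result=res,
                                 method=cfg["profile"]["linkage"])
        (out / "profile.json").write_text(json.dumps(res.to_json()))
    manifest["features"] = "features.csv"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline done: %d areas", len(manifest["areas"]))
    return manifest
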