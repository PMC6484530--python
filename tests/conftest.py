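"""Shared fixtures: small ground-truthed scenes and one default experiment.

The default-experiment fixture runs the full packaged acquisition design
(4 condition presets × 2 replicates × 5 areas of 3×3 tiles) once per session;
it backs the end-to-end population-separation checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecprof.synthgen import (DEFAULT_LAYOUT, SceneParams, _area_seed,
                             render_field, sample_monolayer,
                             scene_params_for)
from ecprof.workflow import analyze_area

SMALL_PARAMS = SceneParams(frame_size=(384, 384), target_cell_count=55)


@pytest.fixture(scope="session")
def small_scene():
    return sample_monolayer(SMALL_PARAMS, seed=1)


@pytest.fixture(scope="session")
def small_field(small_scene):
    return render_field(small_scene, SMALL_PARAMS, seed=1)


@pytest.fixture(scope="session")
def small_analysis(small_field):
    table, row, inter = analyze_area(small_field)
    return table, row, inter


def truth_label_image(scene, shape):
    """Rasterize ground-truth cell polygons into a label image."""
    from skimage.draw import polygon as draw_polygon

    lab = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(scene.cell_polygons, start=1):
        xy = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(xy[:, 0], xy[:, 1], shape)
        lab[rr, cc] = i
    return lab


def match_to_truth(inter, scene, shape):
    """Map predicted cell id → ground-truth cell index via nucleus centroid."""
    tl = truth_label_image(scene, shape)
    nuclei = inter["nuclei"]
    mapping = {}
    for cid in inter["cells"].retained:
        ys, xs = np.nonzero(nuclei.labels == cid)
        if len(ys) == 0:
            continue
        tid = tl[int(round(ys.mean())), int(round(xs.mean()))]
        if tid > 0:
            mapping[cid] = int(tid)
    return mapping


@pytest.fixture(scope="session")
def default_experiment():
    """Analyze the full packaged default experiment (one fixed master seed).

    Returns (area feature rows, cell-model labels, per-area extras).
    """
    layout = DEFAULT_LAYOUT
    rows, labels, extras = [], [], []
    idx = 0
    for model in layout.cell_models:
        for treatment in layout.treatments:
            params = scene_params_for(f"{model}_{treatment}", layout)
            for rep in range(layout.replicates_per_condition):
                for area in range(layout.areas_per_replicate):
                    aseed = _area_seed(3, idx)
                    idx += 1
                    scene = sample_monolayer(params, aseed)
                    field = render_field(scene, params, aseed)
                    table, row, inter = analyze_area(field)
                    rows.append(row)
                    labels.append(model)
                    extras.append({"table": table, "inter": inter,
                                   "scene": scene})
    return rows, labels, extras
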