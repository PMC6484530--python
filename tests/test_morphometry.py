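"""Shape features, STAR features, cell table and the 47-feature registry."""

import json
import math

import numpy as np
import pytest
from skimage.draw import disk as sk_disk

from ecprof.morphometry import (N_FEATURES, feature_registry, registry_names,
                                registry_from_json, registry_to_json,
                                shape_features, star_features)


def _disk_mask(r=20, pad=6):
    m = np.zeros((2 * (r + pad),) * 2, bool)
    rr, cc = sk_disk((r + pad, r + pad), r)
    m[rr, cc] = True
    return m


def test_disk_shape_features():
    sf = shape_features(_disk_mask(20), 1.0)
    assert 0.95 <= sf.roundness <= 1.0
    assert 0.98 <= sf.width_length_ratio <= 1.0
    assert sf.area == pytest.approx(math.pi * 400, rel=0.02)


def test_rectangle_closed_form_moments():
    """40×10 rectangle: λ from discrete-uniform variances, wlr ≈ 1/4."""
    m = np.zeros((60, 30), bool)
    m[10:50, 10:20] = True
    sf = shape_features(m, 1.0)
    assert sf.width_length_ratio == pytest.approx(0.25, abs=0.02)
    exp_len = 4 * math.sqrt((40 ** 2 - 1) / 12)   # 4√λ₁ convention
    exp_wid = 4 * math.sqrt((10 ** 2 - 1) / 12)
    assert sf.length == pytest.approx(exp_len, rel=1e-6)
    assert sf.width == pytest.approx(exp_wid, rel=1e-6)


def test_rotation_invariance_90_degrees():
    m = np.zeros((80, 80), bool)
    m[20:60, 30:46] = True
    a = shape_features(m, 1.0)
    b = shape_features(np.rot90(m).copy(), 1.0)
    for f in ("area", "perimeter", "roundness", "length", "width"):
        assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9)


def test_degenerate_object_rejected():
    m = np.zeros((10, 10), bool)
    m[3, 3:6] = True
    with pytest.raises(ValueError):
        shape_features(m, 1.0)


def test_star_uniform_disk():
    m = _disk_mask(20)
    ch = np.where(m, 100.0, 0.0)
    st = star_features(ch, m, 1.0)
    assert st.symmetry == pytest.approx(1.0, abs=0.01)
    for f in ("tc_030", "tc_040", "tc_050", "tc_060"):
        assert getattr(st, f) == pytest.approx(1.0, abs=0.05)
    assert st.axial_ratio == pytest.approx(1.0, abs=0.02)


def test_star_off_axis_intensity_breaks_symmetry():
    m = np.zeros((60, 100), bool)
    m[15:45, 10:90] = True
    ch = np.where(m, 10.0, 0.0)
    ch[16:30, 12:40] = 400.0
    st = star_features(ch, m, 1.0)
    assert st.symmetry < 0.9


def test_star_zero_intensity_defined_as_zero():
    m = _disk_mask(10)
    st = star_features(np.zeros(m.shape), m, 1.0)
    assert all(v == 0.0 for v in vars(st).values())


def test_star_rotation_stability():
    """Rotating mask+intensity by 90° changes each feature by < 2%."""
    m = np.zeros((80, 80), bool)
    m[20:60, 26:54] = True
    yy, xx = np.mgrid[:80, :80]
    ch = (np.exp(-((yy - 35) ** 2 + (xx - 40) ** 2) / (2 * 9.0 ** 2))
          * 100 + 10) * m
    a = star_features(ch, m, 1.0)
    b = star_features(np.rot90(ch).copy(), np.rot90(m).copy(), 1.0)
    for f in vars(a):
        va, vb = getattr(a, f), getattr(b, f)
        assert vb == pytest.approx(va, rel=0.02, abs=0.02)


def test_threshold_compactness_monotone_for_peaked_intensity():
    m = _disk_mask(25)
    yy, xx = np.mgrid[: m.shape[0], : m.shape[1]]
    c = m.shape[0] / 2
    ch = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * 10.0 ** 2)) * m
    st = star_features(ch, m, 1.0)
    tcs = [st.tc_030, st.tc_040, st.tc_050, st.tc_060]
    # non-decreasing up to raster discretization of the superlevel sets
    assert all(b >= a - 2e-3 for a, b in zip(tcs, tcs[1:]))


def test_registry_has_47_unique_computable_features():
    reg = feature_registry()
    assert len(reg) == N_FEATURES == 47
    names = [d.name for d in reg]
    assert len(set(names)) == 47
    assert all(d.aggregation in ("cell_mean", "area_stat") for d in reg)
    families = {d.family for d in reg}
    assert {"cell_shape", "nucleus_shape", "star_junction", "star_spot",
            "intensity", "junctions", "notch_categories", "notch_clusters",
            "population"} <= families


def test_registry_family_composition():
    from collections import Counter

    by_family = Counter(d.family for d in feature_registry())
    assert by_family["cell_shape"] == 6
    assert by_family["nucleus_shape"] == 7     # 6 shape + area ratio
    assert by_family["star_junction"] == 9
    assert by_family["star_spot"] == 9
    assert by_family["intensity"] == 4
    assert by_family["junctions"] == 4
    assert by_family["notch_categories"] == 3
    assert by_family["notch_clusters"] == 4
    assert by_family["population"] == 1


def test_registry_json_roundtrip(tmp_path):
    p = tmp_path / "registry.json"
    registry_to_json(p)
    assert registry_from_json(p) == feature_registry()
    # stable order across calls
    assert registry_names() == [d.name for d in feature_registry()]


def test_cell_table_complete_and_conserved(small_analysis):
    table, _, inter = small_analysis
    assert len(table) == len(inter["cells"].retained)
    assert not table.isna().any().any()
    assert list(table["cell_id"]) == sorted(table["cell_id"])
    # every cell-mean registry feature is a table column
    for d in feature_registry():
        if d.aggregation == "cell_mean":
            assert d.source in table.columns


def test_border_cells_absent_but_in_adjacency(small_analysis):
    table, _, inter = small_analysis
    cells, graph = inter["cells"], inter["graph"]
    all_ids = {int(v) for v in np.unique(cells.labels) if v > 0}
    border = all_ids - set(cells.retained)
    assert border    # the scene has frame-edge cells
    assert not (set(table["cell_id"]) & border)
    assert border <= set(graph.nodes)


def test_mismatched_stage_outputs_rejected(small_analysis):
    from ecprof.morphometry import build_cell_table

    _, _, inter = small_analysis
    cells, nuclei = inter["cells"], inter["nuclei"]
    bad = {r: np.zeros((8, 8)) for r in ("nuclear", "junction", "spots")}
    with pytest.raises(ValueError, match="mismatched"):
        build_cell_table(cells, nuclei, bad, inter["jset"], inter["notch"])


def test_elongation_recovered_in_measured_wlr():
    """Simulated stretch lowers the measured mean width/length ratio."""
    from ecprof.synthgen import SceneParams, render_field, sample_monolayer
    from ecprof.workflow import analyze_area

    means = {}
    for e in (1.0, 2.0):
        p = SceneParams(frame_size=(384, 384), target_cell_count=55,
                        elongation=e)
        scene = sample_monolayer(p, seed=21)
        field = render_field(scene, p, seed=21)
        _, row, _ = analyze_area(field)
        means[e] = row["cell_width_length_ratio"]
    assert means[2.0] < means[1.0]
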