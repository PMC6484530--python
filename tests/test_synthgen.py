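"""Simulator: determinism, ground-truth invariants, contrast knobs."""

import numpy as np
import pytest
from scipy import stats

from ecprof.synthgen import (InfeasibleDensityError, SceneParams,
                             sample_monolayer, render_field, PRESETS)
from ecprof.synthgen import _polygon_axes

TINY = SceneParams(frame_size=(256, 256), target_cell_count=25)


def test_empty_scene():
    p = TINY.replace(target_cell_count=0)
    scene = sample_monolayer(p, seed=0)
    assert scene.n_cells == 0
    assert scene.adjacency == set()
    assert scene.spots == []


def test_all_negative_forces_no_spots():
    p = TINY.replace(category_probs=(1.0, 0.0, 0.0))
    scene = sample_monolayer(p, seed=2)
    assert all(c == "Nneg" for c in scene.true_category)
    assert scene.spots == []


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SceneParams(category_probs=(0.5, 0.4, 0.2))
    with pytest.raises(ValueError):
        SceneParams(elongation=0.8)
    with pytest.raises(ValueError):
        SceneParams(frame_size=(32, 256))
    with pytest.raises(InfeasibleDensityError):
        sample_monolayer(TINY.replace(target_cell_count=20000), seed=0)


def test_determinism_bit_identical():
    s1 = sample_monolayer(TINY, seed=5)
    s2 = sample_monolayer(TINY, seed=5)
    assert s1.to_json() == s2.to_json()
    f1 = render_field(s1, TINY, seed=5)
    f2 = render_field(s2, TINY, seed=5)
    assert np.array_equal(f1.data, f2.data)


def test_scene_category_spot_invariants():
    scene = sample_monolayer(TINY, seed=3)
    spots_by_cell = {}
    for s in scene.spots:
        spots_by_cell.setdefault(s.cell_id, []).append(s.compartment)
    for cid, cat in enumerate(scene.true_category, start=1):
        comps = spots_by_cell.get(cid, [])
        if cat == "Nneg":
            assert comps == []
        elif cat == "Ncyt":
            assert "cytoplasmic" in comps and "nuclear" not in comps
        else:
            assert "nuclear" in comps


def test_nucleus_inside_cell_polygon():
    scene = sample_monolayer(TINY, seed=4)
    for poly, ell in zip(scene.cell_polygons, scene.nucleus_ellipses):
        assert poly.buffer(1e-6).contains(ell.polygon())


def test_nuclear_spots_inside_nucleus():
    scene = sample_monolayer(TINY, seed=6)
    for s in scene.spots:
        ell = scene.nucleus_ellipses[s.cell_id - 1]
        if s.compartment == "nuclear":
            assert ell.contains(*s.center)
        else:
            assert not ell.contains(*s.center)


def test_category_fraction_binomial_ci():
    """Nnuc frequency over 20 scenes sits inside the exact binomial 95% CI."""
    p = TINY.replace(category_probs=(0.2, 0.3, 0.5))
    k = n = 0
    for seed in range(20):
        scene = sample_monolayer(p, seed=seed)
        k += sum(c == "Nnuc" for c in scene.true_category)
        n += scene.n_cells
    lo, hi = stats.binomtest(k, n, 0.5).proportion_ci(0.95, method="exact")
    assert lo <= 0.5 <= hi


def test_category_frequencies_chisquare():
    """Chi-square GOF vs category_probs not rejected at α=0.01, n ≥ 2000."""
    p = SceneParams(frame_size=(512, 512), target_cell_count=110)
    counts = {"Nneg": 0, "Ncyt": 0, "Nnuc": 0}
    n = 0
    seed = 0
    while n < 2000:
        scene = sample_monolayer(p, seed=seed)
        for c in scene.true_category:
            counts[c] += 1
        n += scene.n_cells
        seed += 1
    obs = np.array([counts[c] for c in ("Nneg", "Ncyt", "Nnuc")])
    exp = np.asarray(p.category_probs) * n
    assert stats.chisquare(obs, exp).pvalue > 0.01


def test_adjacency_matches_bruteforce():
    """Adjacency = polygon border sharing, vs all-pairs brute force."""
    scene = sample_monolayer(TINY.replace(target_cell_count=20), seed=7)
    brute = set()
    polys = scene.cell_polygons
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].boundary.intersection(polys[j].boundary)
            if inter.length > 1e-9:
                brute.add((i + 1, j + 1))
    assert scene.adjacency == brute


def test_elongation_monotone_on_truth():
    """Mean true width/length ratio strictly decreases with elongation."""
    means = []
    for e in (1.0, 1.5, 2.0):
        p = SceneParams(frame_size=(512, 512), target_cell_count=110,
                        elongation=e)
        scene = sample_monolayer(p, seed=11)
        wlr = [_polygon_axes(poly)[2] / _polygon_axes(poly)[1]
               for poly in scene.cell_polygons]
        means.append(np.mean(wlr))
    assert means[0] > means[1] > means[2]


def test_render_empty_scene_is_constant_background():
    p = TINY.replace(target_cell_count=0, noise_sigma=0.0)
    scene = sample_monolayer(p, seed=0)
    field = render_field(scene, p, seed=0)
    assert np.all(field.data == int(p.background_offset))


def test_render_intact_junction_network_is_connected():
    """p_frag=0, jaggedness=0: thresholded borders form one component."""
    from scipy import ndimage as ndi

    p = TINY.replace(junction_fragmentation=0.0, jaggedness=0.0,
                     noise_sigma=0.0)
    scene = sample_monolayer(p, seed=8)
    field = render_field(scene, p, seed=8)
    jc = field.channel("junction").astype(float)
    binary = jc > (p.background_offset + 0.2 * (jc.max() - p.background_offset))
    _, n = ndi.label(binary, structure=np.ones((3, 3), bool))
    assert n == 1


def test_render_spot_at_nuclear_center():
    """The spot channel peaks at a planted nuclear spot."""
    p = TINY.replace(target_cell_count=5, category_probs=(0.0, 0.0, 1.0),
                     spot_rate_nuc=1.0, spot_rate_cyt=0.5, noise_sigma=0.0)
    scene = sample_monolayer(p, seed=9)
    field = render_field(scene, p, seed=9)
    sp = field.channel("spots").astype(float)
    r, c = np.unravel_index(np.argmax(sp), sp.shape)
    d = min(np.hypot(r - s.center[0], c - s.center[1]) for s in scene.spots)
    assert d <= 2.0


def test_presets_known_and_ordered():
    assert set(PRESETS) == {"huvec_basal", "huvec_vegf",
                            "ipsc_basal", "ipsc_vegf"}
    assert PRESETS["huvec_vegf"]["elongation"] > \
        PRESETS["huvec_basal"]["elongation"]
    assert PRESETS["ipsc_basal"]["junction_fragmentation"] > \
        PRESETS["huvec_basal"]["junction_fragmentation"]
    assert PRESETS["ipsc_vegf"]["category_probs"][2] > \
        PRESETS["ipsc_basal"]["category_probs"][2]
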