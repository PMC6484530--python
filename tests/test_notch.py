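"""Spot detection, NOTCH classification, adjacency and contact clusters."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi

from ecprof.notch import (SpotParams, SpotSet, DetectedSpot, cell_adjacency,
                          classify_notch, detect_spots, notch_clusters)
from ecprof.segmentation import LabelMask
from ecprof.synthgen import SceneParams, render_field, sample_monolayer
from ecprof.workflow import analyze_area

from conftest import match_to_truth


def test_constant_image_no_spots():
    assert len(detect_spots(np.full((64, 64), 500.0))) == 0


def test_planted_spots_recovered():
    """Five bright Gaussian spots recovered within 2 px of true centers."""
    rng = np.random.default_rng(1)
    img = rng.normal(100, 5, (128, 128))
    centers = [(20, 20), (20, 100), (64, 64), (100, 30), (108, 108)]
    yy, xx = np.mgrid[:128, :128]
    for r, c in centers:
        img += 50 * 10 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 2.0**2))
    spots = detect_spots(img, SpotParams(dog_sigma=2.0))
    assert len(spots) == 5
    for r, c in centers:
        d = min(np.hypot(s.center[0] - r, s.center[1] - c)
                for s in spots.spots)
        assert d <= 2.0


def test_close_spots_suppressed_to_one():
    img = np.zeros((64, 64))
    yy, xx = np.mgrid[:64, :64]
    for c in (31, 32):
        img += 1000 * np.exp(-((yy - 32) ** 2 + (xx - c) ** 2) / (2 * 1.5**2))
    spots = detect_spots(img, SpotParams(min_separation=5))
    assert len(spots) == 1


def _three_cell_masks():
    cells = np.zeros((30, 90), dtype=np.int32)
    cells[:, :30], cells[:, 30:60], cells[:, 60:] = 1, 2, 3
    nuclei = np.zeros_like(cells)
    for i, c0 in enumerate((10, 40, 70), start=1):
        nuclei[10:20, c0:c0 + 10] = i
    return (LabelMask(cells, "cells"), LabelMask(nuclei, "nuclei"))


def test_classification_definition_case():
    """No spots → Nneg; cytoplasm only → Ncyt; nuclear (+cyto) → Nnuc."""
    cells, nuclei = _three_cell_masks()
    spots = SpotSet([
        DetectedSpot((5, 35), 10.0, 4.0),     # B cytoplasmic
        DetectedSpot((15, 75), 10.0, 4.0),    # C nuclear
        DetectedSpot((5, 65), 10.0, 4.0),     # C cytoplasmic
        DetectedSpot((25, 75), 10.0, 4.0),    # C cytoplasmic
    ])
    res, spots = classify_notch(spots, nuclei, cells)
    assert res.categories == {1: "Nneg", 2: "Ncyt", 3: "Nnuc"}
    for v in res.fractions.values():
        assert v == pytest.approx(100 / 3)
    assert sum(res.fractions.values()) == pytest.approx(100.0)


def test_no_spots_all_negative():
    cells, nuclei = _three_cell_masks()
    res, _ = classify_notch(SpotSet([]), nuclei, cells)
    assert res.fractions == {"Nneg": 100.0, "Ncyt": 0.0, "Nnuc": 0.0}


def test_spot_outside_cells_is_logged_not_classified():
    cells, nuclei = _three_cell_masks()
    cells.labels[0, 0] = 0
    spots = SpotSet([DetectedSpot((0, 0), 5.0, 1.0)])
    res, spots = classify_notch(spots, nuclei, cells)
    assert res.n_outside == 1
    assert spots.spots[0].compartment == "outside"


def test_category_agreement_with_ground_truth(default_experiment):
    """Per-cell agreement with simulator truth ≥ 95% at default noise."""
    rows, labels, extras = default_experiment
    agree = total = 0
    for ex in extras[:4]:   # ≥ 200 cells from the first areas
        inter, scene = ex["inter"], ex["scene"]
        shape = inter["cells"].labels.shape
        mapping = match_to_truth(inter, scene, shape)
        cats = inter["notch"].categories
        for cid, tid in mapping.items():
            if cid in cats:
                total += 1
                agree += cats[cid] == scene.true_category[tid - 1]
    assert total >= 200
    assert agree / total >= 0.95


def test_single_cell_has_no_edges():
    cells = LabelMask(np.ones((20, 20), dtype=np.int32), "cells")
    g = cell_adjacency(cells)
    assert g.number_of_nodes() == 1 and g.number_of_edges() == 0


def test_two_rectangles_share_edge():
    lab = np.zeros((50, 40), dtype=np.int32)
    lab[:25], lab[25:] = 1, 2
    g = cell_adjacency(LabelMask(lab, "cells"), min_shared_border=3)
    assert set(g.edges) == {(1, 2)}


def test_adjacency_equals_bruteforce_scan():
    """Edge set equals an all-pairs boundary scan on random label images."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        seeds = rng.integers(0, 60, size=(20, 2))
        yy, xx = np.mgrid[:60, :60]
        d = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
        lab = np.argmin(d, axis=-1).astype(np.int32) + 1
        g = cell_adjacency(LabelMask(lab, "cells"), min_shared_border=1)
        brute = set()
        ids = np.unique(lab)
        for i in ids:
            for j in ids:
                if i >= j:
                    continue
                mi = lab == i
                grown = ndi.binary_dilation(
                    mi, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
                if np.any(grown & (lab == j)):
                    brute.add((int(i), int(j)))
        assert set(map(tuple, map(sorted, g.edges))) == brute


def test_cluster_summary_hand_case():
    g = nx.Graph()
    g.add_edges_from([(1, 2), (2, 3), (1, 3)])
    g.add_node(4)
    cats = {1: "Nnuc", 2: "Nnuc", 3: "Nnuc", 4: "Nnuc"}
    cs = notch_clusters(g, cats)
    assert sorted(len(c) for c in cs.clusters) == [1, 3]
    assert cs.n_clusters == 2
    assert cs.mean_size == 2.0
    assert cs.max_size == 3
    assert cs.frac_in_multi == 0.75


def test_no_nnuc_cells_zero_summary():
    g = nx.path_graph(4)
    cs = notch_clusters(g, {i: "Nneg" for i in g.nodes})
    assert (cs.n_clusters, cs.mean_size, cs.max_size, cs.frac_in_multi) == \
        (0, 0.0, 0, 0.0)


def test_cluster_partition_equals_bfs_oracle():
    """Component partition equals breadth-first search on 100 random graphs."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(2, 31))
        g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.4),
                                seed=int(rng.integers(2**31)))
        cats = {i: ("Nnuc" if rng.uniform() < 0.5 else "Nneg")
                for i in g.nodes}
        cs = notch_clusters(g, cats)
        # independent BFS oracle
        nnuc = {i for i, c in cats.items() if c == "Nnuc"}
        seen, comps = set(), []
        for s in sorted(nnuc):
            if s in seen:
                continue
            comp, queue = {s}, [s]
            while queue:
                u = queue.pop(0)
                for v in g.neighbors(u):
                    if v in nnuc and v not in comp:
                        comp.add(v)
                        queue.append(v)
            seen |= comp
            comps.append(comp)
        assert sorted(map(sorted, cs.clusters)) == sorted(map(sorted, comps))
        assert sum(len(c) for c in cs.clusters) == len(nnuc)


def test_raising_pi_nuc_raises_measured_activation():
    """π_nuc 0.2 → 0.6 strictly raises %N+/+ and mean cluster size."""
    results = {}
    for pi in (0.2, 0.6):
        p = SceneParams(frame_size=(512, 512), target_cell_count=110,
                        category_probs=(0.2, 0.8 - pi, pi))
        scene = sample_monolayer(p, seed=13)
        field = render_field(scene, p, seed=13)
        _, row, inter = analyze_area(field)
        results[pi] = (row["pct_nnuc"], row["notch_mean_cluster_size"])
    assert results[0.6][0] > results[0.2][0]
    assert results[0.6][1] > results[0.2][1]
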