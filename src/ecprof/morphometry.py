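"""Per-cell morphology, STAR intensity-distribution features and the
canonical 47-feature registry.

Shape features use the ellipse-equivalent axis convention length = 4√λ₁·px,
with λ the eigenvalues of the pixel-coordinate covariance: a uniform disk of
radius R then has length = width = 2R exactly.  The convention is a moment
summary, not a fitted ellipse.  STAR features (Symmetry, Threshold
compactness, Axial, Radial) are dimensionless, bounded intensity-distribution
descriptors evaluated per cell per channel.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton

from .junctions import JunctionSet
from .notch import NotchResult, ClusterSummary
from .segmentation import LabelMask

__all__ = ["ShapeFeatures", "StarFeatures", "FeatureDescriptor",
           "shape_features", "star_features", "build_cell_table",
           "feature_registry", "registry_names", "N_FEATURES"]

log = logging.getLogger(__name__)

N_FEATURES = 47
TC_FRACTIONS = (0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class ShapeFeatures:
    area: float                 # µm²
    perimeter: float            # µm (Crofton, 4 directions)
    roundness: float            # 4πA/P², clipped to 1
    length: float               # µm, 4√λ₁·pixel_size
    width: float                # µm, 4√λ₂·pixel_size
    width_length_ratio: float


@dataclass(frozen=True)
class StarFeatures:
    symmetry: float
    tc_030: float
    tc_040: float
    tc_050: float
    tc_060: float
    axial_ratio: float
    axial_small_length: float   # µm
    radial_mean: float
    radial_rel_deviation: float


def shape_features(mask: np.ndarray, pixel_size: float) -> ShapeFeatures:
    """Morphology of one binary object (≥ 4 px)."""
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx < 4:
        raise ValueError("degenerate object: fewer than 4 pixels")
    area = npx * pixel_size ** 2
    perim = perimeter_crofton(mask, directions=4) * pixel_size
    roundness = min(1.0, 4 * math.pi * area / perim ** 2) if perim > 0 else 1.0
    coords = np.column_stack(np.nonzero(mask)).astype(float)
    cov = np.cov(coords.T, bias=True)   # population moments of the pixel set
    w = np.linalg.eigvalsh(cov)
    lam2, lam1 = max(w[0], 1e-12), max(w[1], 1e-12)
    length = 4 * math.sqrt(lam1) * pixel_size
    width = 4 * math.sqrt(lam2) * pixel_size
    return ShapeFeatures(area, perim, roundness, length, width,
                         min(width / length, 1.0))


def _principal_axis(coords: np.ndarray, weights: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted centroid and principal-axis eigvals/vecs of coordinates."""
    wsum = weights.sum()
    mu = (coords * weights[:, None]).sum(axis=0) / wsum
    d = coords - mu
    cov = (d * weights[:, None]).T @ d / wsum
    lam, vec = np.linalg.eigh(cov)
    return mu, lam, vec   # lam ascending; vec[:, -1] is the major axis


def star_features(channel: np.ndarray, cell_mask: np.ndarray,
                  pixel_size: float) -> StarFeatures:
    """STAR intensity-distribution features of one channel in one cell.

    symmetry: 1 − Σ|I − I_mirror| / (ΣI + ΣI_mirror), mirroring across the
    cell shape's principal axis placed through the intensity centroid (the
    axis direction comes from the binary mask, so off-axis intensity lowers
    symmetry instead of re-orienting the axis).  threshold_compactness(f):
    pixels with I ≥ f·mean(I); TC = (A_f/2π)/m₂ with m₂ their mean squared
    centroid distance (1 for a uniform disk, clipped to 1).  axial: √(λ₂/λ₁)
    of the intensity-weighted covariance and the small-axis length 4√λ₂.
    radial: intensity-weighted mean and standard deviation of the normalized
    distance-to-border d̂.  All features are 0 for a zero-intensity cell.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() < 16:
        raise ValueError("cell mask too small for STAR features (<16 px)")
    vals = np.asarray(channel, dtype=float)[cell_mask]
    total = vals.sum()
    if total <= 0 or not np.isfinite(total):
        log.debug("zero-intensity cell: STAR features set to 0")
        return StarFeatures(*([0.0] * 9))
    coords = np.column_stack(np.nonzero(cell_mask)).astype(float)

    mu, lam, _vec = _principal_axis(coords, vals)
    lam1, lam2 = max(lam[1], 1e-12), max(lam[0], 1e-12)
    axial_ratio = min(math.sqrt(lam2 / lam1), 1.0)
    axial_small = 4 * math.sqrt(lam2) * pixel_size

    # symmetry: reflect across the mask's principal axis through the
    # intensity centroid (mask-based direction, so an off-axis blob is
    # mirrored onto low intensity rather than onto itself)
    _, _, mvec = _principal_axis(coords, np.ones(len(coords)))
    axis = mvec[:, -1]
    d = coords - mu
    along = d @ axis
    perp = d - np.outer(along, axis)
    mirrored = mu + np.outer(along, axis) - perp
    img = np.asarray(channel, dtype=float) * cell_mask
    i_mirror = ndi.map_coordinates(img, mirrored.T, order=1, mode="constant")
    symmetry = 1.0 - np.abs(vals - i_mirror).sum() / (total + i_mirror.sum())
    symmetry = float(np.clip(symmetry, 0.0, 1.0))

    mean_i = total / len(vals)
    tcs = []
    for f in TC_FRACTIONS:
        sel = vals >= f * mean_i
        a_f = int(sel.sum())
        if a_f <= 4:
            tcs.append(1.0)
            continue
        pts = coords[sel]
        cen = pts.mean(axis=0)
        m2 = ((pts - cen) ** 2).sum(axis=1).mean()
        tcs.append(min((a_f / (2 * math.pi)) / m2, 1.0) if m2 > 0 else 1.0)

    # radial: distance to the cell border, normalized by its maximum
    dist = ndi.distance_transform_edt(cell_mask)
    dmax = dist.max()
    dhat = (dist[cell_mask] / dmax) if dmax > 0 else dist[cell_mask]
    w = vals / total
    radial_mean = float((w * dhat).sum())
    radial_sd = float(math.sqrt(max((w * (dhat - radial_mean) ** 2).sum(),
                                    0.0)))
    return StarFeatures(symmetry, *tcs, axial_ratio, axial_small,
                        radial_mean, radial_sd)


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    aggregation: str      # "cell_mean" | "area_stat"
    source: str           # cell-table column or area-stat key


def feature_registry() -> list[FeatureDescriptor]:
    """The canonical ordered 47-feature registry.

    Composition: 6 cell-shape + 6 nucleus-shape + 1 nucleus/cell area ratio
    + 9 STAR (junction channel) + 9 STAR (spot channel) + 4 mean intensities
    + 4 junction statistics + 3 NOTCH category percentages + 4 NOTCH cluster
    features + 1 cell count = 47.
    """
    reg: list[FeatureDescriptor] = []

    def cm(name, family):
        reg.append(FeatureDescriptor(name, family, "cell_mean", name))

    def ar(name, family):
        reg.append(FeatureDescriptor(name, family, "area_stat", name))

    shape_cols = ("area", "perimeter", "roundness", "length", "width",
                  "width_length_ratio")
    for col in shape_cols:
        cm(f"cell_{col}", "cell_shape")
    for col in shape_cols:
        cm(f"nucleus_{col}", "nucleus_shape")
    cm("nucleus_cell_area_ratio", "nucleus_shape")
    star_cols = ("symmetry", "tc_030", "tc_040", "tc_050", "tc_060",
                 "axial_ratio", "axial_small_length", "radial_mean",
                 "radial_rel_deviation")
    for col in star_cols:
        cm(f"junction_{col}", "star_junction")
    for col in star_cols:
        cm(f"spot_{col}", "star_spot")
    for name in ("mean_junction_intensity_cell", "mean_spot_intensity_cyto",
                 "mean_spot_intensity_nucleus",
                 "mean_nuclear_intensity_nucleus"):
        cm(name, "intensity")
    ar("jn", "junctions")
    cm("jn_mean_object_area", "junctions")
    cm("jn_ring_area_fraction", "junctions")
    cm("jn_object_mean_intensity", "junctions")
    for name in ("pct_nneg", "pct_ncyt", "pct_nnuc"):
        ar(name, "notch_categories")
    for name in ("notch_n_clusters", "notch_mean_cluster_size",
                 "notch_max_cluster_size", "notch_frac_in_multi"):
        ar(name, "notch_clusters")
    ar("cell_count", "population")

    assert len(reg) == N_FEATURES
    assert len({d.name for d in reg}) == N_FEATURES
    return reg


def registry_names() -> list[str]:
    return [d.name for d in feature_registry()]


def registry_to_json(path) -> None:
    from pathlib import Path
    Path(path).write_text(json.dumps([asdict(d) for d in feature_registry()],
                                     indent=1))


def registry_from_json(path) -> list[FeatureDescriptor]:
    from pathlib import Path
    return [FeatureDescriptor(**d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------

def build_cell_table(cells: LabelMask, nuclei: LabelMask,
                     channels: dict[str, np.ndarray],
                     jset: JunctionSet, notch: NotchResult,
                     clusters: ClusterSummary | None = None,
                     area_name: str = "area") -> pd.DataFrame:
    """Assemble one complete record per retained cell.

    ``channels`` maps role → 2D array for "nuclear", "junction", "spots".
    Rows are ordered by cell id; border-excluded cells are absent.  Raises
    if stage outputs disagree on shape (mismatched areas).
    """
    for ch in channels.values():
        if ch.shape != cells.labels.shape:
            raise ValueError("stage outputs come from mismatched areas")
    if nuclei.labels.shape != cells.labels.shape:
        raise ValueError("stage outputs come from mismatched areas")

    cluster_of: dict[int, int] = {}
    if clusters is not None:
        for k, comp in enumerate(clusters.clusters, start=1):
            for cid in comp:
                cluster_of[cid] = k

    ps = cells.pixel_size
    rows = []
    slices = ndi.find_objects(cells.labels)
    for cid in sorted(cells.retained):
        sl = slices[cid - 1]
        if sl is None:
            continue
        cmask = cells.labels[sl] == cid
        nmask = nuclei.labels[sl] == cid
        if cmask.sum() < 16 or nmask.sum() < 4:
            log.debug("cell %d degenerate, excluded", cid)
            continue
        try:
            cshape = shape_features(cmask, ps)
            nshape = shape_features(nmask, ps)
        except ValueError:
            continue
        rec: dict[str, object] = {"area_id": area_name, "cell_id": cid,
                                  "nucleus_id": cid}
        for pre, sf in (("cell", cshape), ("nucleus", nshape)):
            for k, v in asdict(sf).items():
                rec[f"{pre}_{k}"] = v
        rec["nucleus_cell_area_ratio"] = nshape.area / cshape.area

        jch = channels["junction"][sl]
        sch = channels["spots"][sl]
        nch = channels["nuclear"][sl]
        for pre, ch in (("junction", jch), ("spot", sch)):
            st = star_features(ch, cmask, ps)
            for k, v in asdict(st).items():
                rec[f"{pre}_{k}"] = v
        cyto = cmask & ~nmask
        rec["mean_junction_intensity_cell"] = float(jch[cmask].mean())
        rec["mean_spot_intensity_cyto"] = (float(sch[cyto].mean())
                                           if cyto.any() else 0.0)
        rec["mean_spot_intensity_nucleus"] = float(sch[nmask].mean())
        rec["mean_nuclear_intensity_nucleus"] = float(nch[nmask].mean())

        rec["jn_count"] = jset.per_cell_counts.get(cid, 0)
        rec["jn_mean_object_area"] = jset.per_cell_mean_object_area.get(
            cid, 0.0)
        ring = jset.per_cell_ring.get(cid, 0)
        rec["jn_ring_area_fraction"] = (
            jset.per_cell_object_px.get(cid, 0) / ring if ring else 0.0)
        rec["jn_object_mean_intensity"] = \
            jset.per_cell_object_mean_intensity.get(cid, 0.0)
        rec["notch_category"] = notch.categories.get(cid, "Nneg")
        rec["cluster_id"] = cluster_of.get(cid, 0)
        rows.append(rec)

    columns = _cell_table_columns()
    df = pd.DataFrame(rows, columns=columns)
    return df


def _cell_table_columns() -> list[str]:
    cols = ["area_id", "cell_id", "nucleus_id"]
    shape_cols = ("area", "perimeter", "roundness", "length", "width",
                  "width_length_ratio")
    cols += [f"cell_{c}" for c in shape_cols]
    cols += [f"nucleus_{c}" for c in shape_cols]
    cols += ["nucleus_cell_area_ratio"]
    star_cols = ("symmetry", "tc_030", "tc_040", "tc_050", "tc_060",
                 "axial_ratio", "axial_small_length", "radial_mean",
                 "radial_rel_deviation")
    cols += [f"junction_{c}" for c in star_cols]
    cols += [f"spot_{c}" for c in star_cols]
    cols += ["mean_junction_intensity_cell", "mean_spot_intensity_cyto",
             "mean_spot_intensity_nucleus", "mean_nuclear_intensity_nucleus",
             "jn_count", "jn_mean_object_area", "jn_ring_area_fraction",
             "jn_object_mean_intensity", "notch_category", "cluster_id"]
    return cols
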