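"""Ground-truthed synthetic confluent-endothelium scenes.

The generator emulates a confluent EC monolayer as an anisotropic Voronoi
tessellation of blue-noise seeds, with one nucleus ellipse per cell, per-cell
NOTCH activation categories and activation spots, and a three-channel renderer
(nuclear stain / junction marker / activation spots).  Every scene carries its
full ground truth so downstream segmentation, junction and classification
stages can be validated without real microscope data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import shapely.ops
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, Polygon, box

from .imaging_io import CHANNEL_ROLES, FieldImage, write_field

__all__ = [
    "SceneParams",
    "GroundTruthScene",
    "ExperimentLayout",
    "InfeasibleDensityError",
    "sample_monolayer",
    "render_field",
    "generate_experiment",
    "PRESETS",
    "DEFAULT_LAYOUT",
]

CATEGORIES = ("Nneg", "Ncyt", "Nnuc")


class InfeasibleDensityError(ValueError):
    """Requested cell count cannot be packed into the frame."""


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic monolayer scene.

    Units: lengths in pixels unless stated; ``pixel_size`` in µm/px;
    intensities on the 16-bit output scale.
    """

    frame_size: tuple[int, int] = (576, 576)
    pixel_size: float = 0.5
    target_cell_count: int = 120
    elongation: float = 1.2          # >= 1, anisotropic metric stretch
    jaggedness: float = 1.5          # px, boundary perturbation amplitude
    junction_fragmentation: float = 0.2   # p_frag, per-segment deletion prob
    segment_length: float = 16.0     # px
    junction_width: float = 2.5      # px, Gaussian cross-profile width
    category_probs: tuple[float, float, float] = (0.20, 0.30, 0.50)
    spot_rate_cyt: float = 3.0       # mean spots/cell, > 0
    spot_rate_nuc: float = 2.0
    spot_sigma: float = 1.5          # px
    background_offset: float = 200.0
    noise_sigma: float = 25.0
    psf_sigma: float = 0.8
    nucleus_area_fraction: float = 0.15
    nuclear_amp: float = 3000.0
    junction_amp: float = 4000.0
    spot_amp: float = 3000.0

    def __post_init__(self) -> None:
        r, c = self.frame_size
        if r < 64 or c < 64:
            raise ValueError("frame dimensions must be >= 64 px")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if not 0 <= self.junction_fragmentation <= 1:
            raise ValueError("junction_fragmentation must be in [0, 1]")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        if min(self.category_probs) < 0:
            raise ValueError("category_probs must be non-negative")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if self.spot_rate_cyt <= 0 or self.spot_rate_nuc <= 0:
            raise ValueError("spot rates must be > 0")
        if self.target_cell_count < 0:
            raise ValueError("target_cell_count must be >= 0")

    def replace(self, **kw) -> "SceneParams":
        return dataclasses.replace(self, **kw)


@dataclass
class Spot:
    cell_id: int
    compartment: str            # "nuclear" | "cytoplasmic"
    center: tuple[float, float]  # (row, col) px

    def to_json(self) -> dict:
        return {"cell_id": self.cell_id, "compartment": self.compartment,
                "center": list(self.center)}


@dataclass
class NucleusEllipse:
    center: tuple[float, float]   # (row, col)
    axes: tuple[float, float]     # semi-axes (major, minor), px
    angle: float                  # radians, major axis vs row direction

    def contains(self, r: float, c: float) -> bool:
        dr, dc = r - self.center[0], c - self.center[1]
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        a, b = self.axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def polygon(self, n: int = 64) -> Polygon:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        a, b = self.axes
        u, v = a * np.cos(t), b * np.sin(t)
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        r = self.center[0] + u * ca - v * sa
        c = self.center[1] + u * sa + v * ca
        return Polygon(np.column_stack([r, c]))

    def to_json(self) -> dict:
        return {"center": list(self.center), "axes": list(self.axes),
                "angle": self.angle}


@dataclass
class GroundTruthScene:
    """Simulator output: geometry, per-cell truth and provenance."""

    cell_polygons: list[Polygon]
    nucleus_ellipses: list[NucleusEllipse]
    true_category: list[str]
    spots: list[Spot]
    adjacency: set[tuple[int, int]]   # unordered 1-based cell-id pairs (i<j)
    params_used: SceneParams
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_polygons)

    def to_json(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "cell_polygons": [list(map(list, p.exterior.coords))
                              for p in self.cell_polygons],
            "nucleus_ellipses": [e.to_json() for e in self.nucleus_ellipses],
            "true_category": list(self.true_category),
            "spots": [s.to_json() for s in self.spots],
            "adjacency": sorted(map(list, self.adjacency)),
            "seed": self.seed,
            "params_used": dataclasses.asdict(self.params_used),
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruthScene":
        pd = dict(d["params_used"])
        pd["frame_size"] = tuple(pd["frame_size"])
        pd["category_probs"] = tuple(pd["category_probs"])
        return cls(
            cell_polygons=[Polygon(c) for c in d["cell_polygons"]],
            nucleus_ellipses=[NucleusEllipse(tuple(e["center"]),
                                             tuple(e["axes"]), e["angle"])
                              for e in d["nucleus_ellipses"]],
            true_category=list(d["true_category"]),
            spots=[Spot(s["cell_id"], s["compartment"], tuple(s["center"]))
                   for s in d["spots"]],
            adjacency={tuple(p) for p in d["adjacency"]},
            params_used=SceneParams(**pd),
            seed=d["seed"],
        )


@dataclass(frozen=True)
class ExperimentLayout:
    """Acquisition design: conditions × replicates × areas × tile grid."""

    cell_models: tuple[str, ...] = ("huvec", "ipsc")
    treatments: tuple[str, ...] = ("basal", "vegf")
    replicates_per_condition: int = 2
    areas_per_replicate: int = 5
    tile_grid: tuple[int, int] = (3, 3)
    tile_overlap_frac: float = 0.0005
    tile_size: tuple[int, int] = (192, 192)

    def __post_init__(self) -> None:
        if min(self.replicates_per_condition, self.areas_per_replicate) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.tile_grid) < 1:
            raise ValueError("tile grid must be >= 1x1")
        if not 0 <= self.tile_overlap_frac < 0.5:
            raise ValueError("tile_overlap_frac must be in [0, 0.5)")

    @property
    def n_areas(self) -> int:
        return (len(self.cell_models) * len(self.treatments)
                * self.replicates_per_condition * self.areas_per_replicate)

    def area_shape(self) -> tuple[int, int]:
        """Mosaic shape implied by the tile grid and overlap."""
        out = []
        for n, dim in zip(self.tile_grid, self.tile_size):
            step = int(round(dim * (1 - self.tile_overlap_frac)))
            out.append((n - 1) * step + dim)
        return tuple(out)


DEFAULT_LAYOUT = ExperimentLayout()

# Phenotype presets.  Only the orderings between them are meaningful:
# VEGF stretches cells (higher elongation); the progenitor model forms a
# sparser monolayer of larger cells (cell_count_factor) with looser, more
# fragmented junctions (higher p_frag) and lower basal NOTCH activation
# (higher π_neg, lower π_nuc), with VEGF shifting it toward nuclear
# activation.  ``cell_count_factor`` scales the frame's target cell count.
PRESETS: dict[str, dict] = {
    "huvec_basal": dict(elongation=1.15, junction_fragmentation=0.15,
                        category_probs=(0.10, 0.25, 0.65),
                        cell_count_factor=1.0),
    "huvec_vegf": dict(elongation=1.6, junction_fragmentation=0.18,
                       category_probs=(0.10, 0.25, 0.65),
                       cell_count_factor=1.0),
    "ipsc_basal": dict(elongation=1.35, junction_fragmentation=0.45,
                       category_probs=(0.30, 0.50, 0.20),
                       cell_count_factor=0.7),
    "ipsc_vegf": dict(elongation=1.55, junction_fragmentation=0.55,
                      category_probs=(0.25, 0.30, 0.45),
                      cell_count_factor=0.7),
}


# ---------------------------------------------------------------------------
# Seed placement and tessellation
# ---------------------------------------------------------------------------

def _poisson_disc(rng: np.random.Generator, shape: tuple[float, float],
                  n: int, min_dist: float, max_tries_per_point: int = 300
                  ) -> np.ndarray:
    """Dart-throwing blue-noise sampler with grid acceleration."""
    cell = min_dist / math.sqrt(2)
    gr = int(math.ceil(shape[0] / cell)), int(math.ceil(shape[1] / cell))
    grid = -np.ones(gr, dtype=int)
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(pts) < n:
        if tries >= budget:
            raise InfeasibleDensityError(
                f"infeasible density: placed {len(pts)}/{n} seeds at "
                f"min distance {min_dist:.1f}px in frame {shape}")
        tries += 1
        p = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
        gi, gj = int(p[0] / cell), int(p[1] / cell)
        ok = True
        for ii in range(max(gi - 2, 0), min(gi + 3, gr[0])):
            for jj in range(max(gj - 2, 0), min(gj + 3, gr[1])):
                k = grid[ii, jj]
                if k >= 0:
                    q = pts[k]
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_dist ** 2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            grid[gi, gj] = len(pts)
            pts.append(p)
    return np.asarray(pts, dtype=float)


def _voronoi_cells(seeds: np.ndarray, frame: tuple[float, float]
                   ) -> list[Polygon]:
    """Voronoi polygons of ``seeds`` clipped to the frame, in seed order."""
    frame_box = box(0.0, 0.0, frame[0], frame[1])
    mp = shapely.multipoints(seeds)
    cells = shapely.voronoi_polygons(mp, extend_to=frame_box.buffer(10),
                                     ordered=True)
    return [shapely.intersection(g, frame_box) for g in cells.geoms]


def _smooth_displacement(rng: np.random.Generator, shape: tuple[int, int],
                         amplitude: float, corr: float = 8.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random vector field with pointwise std ≈ amplitude."""
    fields = []
    for _ in range(2):
        f = gaussian_filter(rng.standard_normal(shape), corr, mode="reflect")
        s = f.std()
        fields.append(f * (amplitude / s) if s > 0 else f * 0.0)
    return fields[0], fields[1]


def _densify(poly: Polygon, max_edge: float = 3.0) -> Polygon:
    return shapely.segmentize(poly, max_edge)


def _warp_polygon(poly: Polygon, dr: np.ndarray, dc: np.ndarray) -> Polygon:
    coords = np.asarray(poly.exterior.coords)
    R, C = dr.shape
    ri = np.clip(coords[:, 0].round().astype(int), 0, R - 1)
    ci = np.clip(coords[:, 1].round().astype(int), 0, C - 1)
    # frame-edge vertices stay pinned so the tessellation keeps covering it
    on_edge = ((coords[:, 0] <= 0) | (coords[:, 0] >= R) |
               (coords[:, 1] <= 0) | (coords[:, 1] >= C))
    out = coords.copy()
    out[~on_edge, 0] += dr[ri, ci][~on_edge]
    out[~on_edge, 1] += dc[ri, ci][~on_edge]
    p = Polygon(out)
    return p if p.is_valid else p.buffer(0)


def _polygon_axes(poly: Polygon) -> tuple[float, float, float]:
    """(angle of major axis, sqrt eigvals) from vertex second moments."""
    xy = np.asarray(_densify(poly, 2.0).exterior.coords)[:-1]
    xy = xy - xy.mean(axis=0)
    cov = np.cov(xy.T)
    w, v = np.linalg.eigh(cov)
    major = v[:, np.argmax(w)]
    return math.atan2(major[1], major[0]), math.sqrt(max(w.max(), 1e-9)), \
        math.sqrt(max(w.min(), 1e-9))


def _fit_nucleus(poly: Polygon, area_fraction: float) -> NucleusEllipse:
    """Ellipse of ~area_fraction×cell area, long-axis aligned, inside poly."""
    angle, s1, s2 = _polygon_axes(poly)
    target = area_fraction * poly.area
    ratio = max(min(s2 / s1, 1.0), 0.45)   # milder anisotropy than the cell
    a = math.sqrt(target / (math.pi * ratio))
    b = a * ratio
    cen = poly.representative_point() if not poly.contains(poly.centroid) \
        else poly.centroid
    ell = NucleusEllipse((cen.x, cen.y), (a, b), angle)
    for _ in range(40):
        if poly.contains(ell.polygon()):
            return ell
        ell = NucleusEllipse(ell.center, (ell.axes[0] * 0.92,
                                          ell.axes[1] * 0.92), angle)
    return ell


def _adjacency_from_polygons(polys: list[Polygon]) -> set[tuple[int, int]]:
    """Cells adjacent iff their polygons share a border of positive length."""
    adj: set[tuple[int, int]] = set()
    tree = shapely.STRtree(polys)
    for i, p in enumerate(polys):
        for j in tree.query(p):
            j = int(j)
            if j <= i:
                continue
            inter = shapely.intersection(p.boundary, polys[j].boundary)
            if inter.length > 1e-9:
                adj.add((i + 1, j + 1))
    return adj


def _sample_in_polygon(rng: np.random.Generator, poly: Polygon,
                       exclude: NucleusEllipse | None, margin: float,
                       n_tries: int = 400) -> tuple[float, float] | None:
    """Uniform point in poly, ≥margin from border, outside grown nucleus."""
    shrunk = poly.buffer(-margin)
    if shrunk.is_empty:
        shrunk = poly
    minr, minc, maxr, maxc = shrunk.bounds
    for _ in range(n_tries):
        r = rng.uniform(minr, maxr)
        c = rng.uniform(minc, maxc)
        if not shrunk.contains(Point(r, c)):
            continue
        if exclude is not None:
            a, b = exclude.axes
            grown = NucleusEllipse(exclude.center,
                                   (a + margin, b + margin), exclude.angle)
            if grown.contains(r, c):
                continue
        return (r, c)
    return None


def _sample_in_ellipse(rng: np.random.Generator, ell: NucleusEllipse,
                       shrink: float = 0.65) -> tuple[float, float]:
    u = math.sqrt(rng.uniform()) * shrink
    t = rng.uniform(0, 2 * math.pi)
    a, b = ell.axes
    uu, vv = a * u * math.cos(t), b * u * math.sin(t)
    ca, sa = math.cos(ell.angle), math.sin(ell.angle)
    return (ell.center[0] + uu * ca - vv * sa,
            ell.center[1] + uu * sa + vv * ca)


def sample_monolayer(params: SceneParams, seed: int) -> GroundTruthScene:
    """Sample a ground-truthed confluent monolayer scene.

    Seeds are blue-noise (Poisson-disc) samples placed under an anisotropic
    metric — row coordinates are stretched by ``elongation`` before sampling
    and tessellation, so mapping back yields cells elongated along rows.
    Cell polygons are the Voronoi regions clipped to the frame, optionally
    warped by a smooth displacement field of amplitude ``jaggedness``.
    Deterministic for fixed ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    R, C = params.frame_size
    n = params.target_cell_count
    if n == 0:
        return GroundTruthScene([], [], [], [], set(), params, seed)

    # transformed (isotropic) space: rows scaled up by elongation
    tshape = (R * params.elongation, float(C))
    area_per_cell = tshape[0] * tshape[1] / n
    min_dist = 0.72 * math.sqrt(area_per_cell)
    if min_dist < 2.0:
        raise InfeasibleDensityError(
            f"infeasible density: {n} cells in frame {params.frame_size}")
    seeds_t = _poisson_disc(rng, tshape, n, min_dist)
    polys_t = _voronoi_cells(seeds_t, tshape)
    # map back: shrink rows → cells elongated along columns-of-constant-row?
    # (divide row coordinate by elongation: isotropic cells become wider in
    #  the column direction relative to rows, i.e. elongated along rows⁻¹)
    polys = [shapely.transform(
        p, lambda a: np.column_stack([a[:, 0] / params.elongation, a[:, 1]]))
        for p in polys_t]

    if params.jaggedness > 0:
        dr, dc = _smooth_displacement(rng, (R, C), params.jaggedness)
        polys = [_warp_polygon(p, dr, dc) for p in polys]

    adjacency = _adjacency_from_polygons(polys)
    nuclei = [_fit_nucleus(p, params.nucleus_area_fraction) for p in polys]

    cats = [CATEGORIES[k] for k in
            rng.choice(3, size=n, p=np.asarray(params.category_probs))]

    spots: list[Spot] = []
    for cid, (poly, nuc, cat) in enumerate(zip(polys, nuclei, cats), start=1):
        if cat == "Nneg":
            continue
        if cat == "Ncyt":
            n_cyt = 1 + rng.poisson(params.spot_rate_cyt - 1)
            n_nuc = 0
        else:
            n_nuc = 1 + rng.poisson(params.spot_rate_nuc - 1)
            n_cyt = int(rng.poisson(max(params.spot_rate_cyt - 1, 0.0)))
        for _ in range(n_nuc):
            spots.append(Spot(cid, "nuclear", _sample_in_ellipse(rng, nuc)))
        placed = 0
        for _ in range(n_cyt):
            p = _sample_in_polygon(rng, poly, nuc, margin=3.0)
            if p is not None:
                spots.append(Spot(cid, "cytoplasmic", p))
                placed += 1
        if cat == "Ncyt" and placed == 0:
            # category invariant requires >=1 cytoplasmic spot
            p = _sample_in_polygon(rng, poly, nuc, margin=1.5)
            spots.append(Spot(cid, "cytoplasmic",
                              p if p is not None
                              else (poly.centroid.x, poly.centroid.y)))

    return GroundTruthScene(polys, nuclei, cats, spots, adjacency,
                            params, seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _border_lines(scene: GroundTruthScene) -> shapely.geometry.base.BaseGeometry:
    if not scene.cell_polygons:
        return LineString()
    return shapely.ops.unary_union(
        [p.boundary for p in scene.cell_polygons])


def _iter_lines(geom) -> list[LineString]:
    if geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, LineString)]


def _draw_polyline(acc: np.ndarray, line: LineString, value: float = 1.0
                   ) -> None:
    """Accumulate a 1-px-wide polyline by dense point sampling."""
    length = line.length
    if length == 0:
        return
    n = max(int(math.ceil(length / 0.5)) + 1, 2)
    pts = shapely.line_interpolate_point(line, np.linspace(0, length, n))
    r = np.clip(np.round([p.x for p in pts]).astype(int), 0, acc.shape[0] - 1)
    c = np.clip(np.round([p.y for p in pts]).astype(int), 0, acc.shape[1] - 1)
    acc[r, c] = value


def _fill_ellipse(acc: np.ndarray, ell: NucleusEllipse, value: float) -> None:
    from skimage.draw import polygon as draw_polygon
    coords = np.asarray(ell.polygon(96).exterior.coords)
    rr, cc = draw_polygon(coords[:, 0], coords[:, 1], acc.shape)
    acc[rr, cc] = value


def render_field(scene: GroundTruthScene, params: SceneParams, seed: int
                 ) -> FieldImage:
    """Render the three stained channels of a scene to a 16-bit field.

    Channel order is fixed as [nuclear, junction, spots].  Cell–cell borders
    are cut into ``segment_length`` chunks; each chunk is independently
    interrupted with probability ``junction_fragmentation`` by carving a
    short gap out of its middle before drawing.  The expected number of
    discontinuities per border therefore grows monotonically with
    ``junction_fragmentation`` over the whole [0, 1] range, which is the
    generative knob behind discontinuous ("active") junctions.
    """
    rng = np.random.default_rng(seed)
    R, C = params.frame_size
    nuclear = np.zeros((R, C), dtype=float)
    junction = np.zeros((R, C), dtype=float)
    spots_ch = np.zeros((R, C), dtype=float)

    for ell in scene.nucleus_ellipses:
        _fill_ellipse(nuclear, ell, params.nuclear_amp)

    mask = np.zeros((R, C), dtype=float)
    for line in _iter_lines(_border_lines(scene)):
        L = line.length
        if L <= params.segment_length:
            segs = [(0.0, L)]
        else:
            k = int(math.ceil(L / params.segment_length))
            edges = np.linspace(0.0, L, k + 1)
            segs = list(zip(edges[:-1], edges[1:]))
        gap_frac = 0.45   # fraction of a segment removed per interruption
        for s0, s1 in segs:
            if rng.uniform() < params.junction_fragmentation:
                mid, half = 0.5 * (s0 + s1), 0.5 * gap_frac * (s1 - s0)
                _draw_polyline(mask, shapely.ops.substring(line, s0,
                                                           mid - half))
                _draw_polyline(mask, shapely.ops.substring(line, mid + half,
                                                           s1))
            else:
                _draw_polyline(mask, shapely.ops.substring(line, s0, s1))
    sigma_j = params.junction_width / 2.0
    junction = gaussian_filter(mask, sigma_j)
    if junction.max() > 0:
        junction *= params.junction_amp / junction.max()

    if scene.spots:
        amp = params.spot_amp * 2 * math.pi * params.spot_sigma ** 2
        for s in scene.spots:
            r, c = int(round(s.center[0])), int(round(s.center[1]))
            if 0 <= r < R and 0 <= c < C:
                spots_ch[r, c] += amp
        spots_ch = gaussian_filter(spots_ch, params.spot_sigma)

    chans = []
    for ch in (nuclear, junction, spots_ch):
        if params.psf_sigma > 0:
            ch = gaussian_filter(ch, params.psf_sigma)
        ch = ch + params.background_offset
        if params.noise_sigma > 0:
            ch = ch + rng.normal(0, params.noise_sigma, ch.shape)
        chans.append(np.clip(ch, 0, 65535))
    data = np.stack(chans).astype(np.uint16)
    return FieldImage(data=data, channel_roles=list(CHANNEL_ROLES),
                      pixel_size=params.pixel_size)


# ---------------------------------------------------------------------------
# Experiment generation
# ---------------------------------------------------------------------------

def _area_seed(master_seed: int, index: int) -> int:
    """Counter-based per-area seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))

def cut_tiles(area: FieldImage, grid: tuple[int, int], overlap_frac: float,
              tile_size: tuple[int, int]) -> list[tuple[int, int, FieldImage]]:
    """Cut an area image into an overlapping tile grid (row, col, tile)."""
    out = []
    steps = [int(round(d * (1 - overlap_frac))) for d in tile_size]
    for i in range(grid[0]):
        for j in range(grid[1]):
            r0, c0 = i * steps[0], j * steps[1]
            sub = area.data[:, r0:r0 + tile_size[0], c0:c0 + tile_size[1]]
            out.append((i, j, FieldImage(sub.copy(), list(area.channel_roles),
                                         area.pixel_size, origin=(r0, c0))))
    return out


def scene_params_for(preset: str, layout: ExperimentLayout,
                     base: SceneParams | None = None) -> SceneParams:
    if preset not in PRESETS:
        raise KeyError(f"unknown preset name: {preset!r}; "
                       f"known: {sorted(PRESETS)}")
    base = base or SceneParams()
    shape = layout.area_shape()
    over = dict(PRESETS[preset])
    factor = over.pop("cell_count_factor", 1.0)
    scale = (shape[0] * shape[1]) / (base.frame_size[0] * base.frame_size[1])
    return base.replace(frame_size=shape,
                        target_cell_count=max(int(round(
                            base.target_cell_count * scale * factor)), 1),
                        **over)


def generate_experiment(layout: ExperimentLayout, seed: int, out_dir,
                        base_params: SceneParams | None = None) -> dict:
    """Simulate the full acquisition design and write tiles + ground truth.

    For every cell model × treatment × replicate × area one area-sized scene
    is sampled and rendered, cut into the overlapping tile grid, and written
    as multi-page TIFF tiles with a per-area ground-truth JSON.  Returns the
    manifest (also written to ``out_dir/manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    areas = []
    idx = 0
    for model in layout.cell_models:
        for treatment in layout.treatments:
            preset = f"{model}_{treatment}"
            params = scene_params_for(preset, layout, base_params)
            for rep in range(1, layout.replicates_per_condition + 1):
                for area in range(1, layout.areas_per_replicate + 1):
                    aseed = _area_seed(seed, idx)
                    idx += 1
                    scene = sample_monolayer(params, aseed)
                    field = render_field(scene, params, aseed)
                    name = f"{preset}_r{rep}_a{area}"
                    adir = out_dir / name
                    adir.mkdir(exist_ok=True)
                    tile_paths = []
                    for i, j, tile in cut_tiles(field, layout.tile_grid,
                                                layout.tile_overlap_frac,
                                                layout.tile_size):
                        tp = adir / f"tile_{i}_{j}.tif"
                        write_field(tile, tp)
                        tile_paths.append({"row": i, "col": j,
                                           "path": str(tp.relative_to(out_dir))})
                    gt_path = adir / "ground_truth.json"
                    gt_path.write_text(json.dumps(scene.to_json()))
                    areas.append({
                        "name": name, "cell_model": model,
                        "treatment": treatment, "replicate": rep,
                        "area": area, "seed": aseed,
                        "tile_grid": list(layout.tile_grid),
                        "tile_overlap_frac": layout.tile_overlap_frac,
                        "tiles": tile_paths,
                        "ground_truth": str(gt_path.relative_to(out_dir)),
                    })
    manifest = {"schema_version": 1, "master_seed": seed,
                "layout": {
                    "cell_models": list(layout.cell_models),
                    "treatments": list(layout.treatments),
                    "replicates_per_condition": layout.replicates_per_condition,
                    "areas_per_replicate": layout.areas_per_replicate,
                    "tile_grid": list(layout.tile_grid),
                    "tile_overlap_frac": layout.tile_overlap_frac,
                    "tile_size": list(layout.tile_size)},
                "areas": areas}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
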