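"""NOTCH-activation spot detection, per-cell classification and clusters.

Activated NOTCH (cleaved intracellular domain) appears as bright subcellular
spots.  Each cell is classified by where its spots sit: no spots → N-/-
(inactive); cytoplasmic only → N+/- (activated, not transcriptionally
active); any nuclear spot → N+/+ (putatively transcriptionally active;
nucleus-only cells are grouped here too).  Contact clusters of N+/+ cells on
the cell-adjacency graph give population-context features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .segmentation import LabelMask

__all__ = ["SpotParams", "SpotSet", "NotchResult", "ClusterSummary",
           "detect_spots", "classify_notch", "cell_adjacency",
           "notch_clusters", "CATEGORY_LABELS"]

log = logging.getLogger(__name__)

CATEGORY_LABELS = {"Nneg": "N-/-", "Ncyt": "N+/-", "Nnuc": "N+/+"}


@dataclass(frozen=True)
class SpotParams:
    dog_sigma: float = 1.5       # px, inner DoG scale; outer = 1.6×
    min_separation: int = 4      # px, non-maximum suppression radius
    t_spot: float = 8.0          # threshold in robust-MAD units
    k: float = 1.6               # DoG scale ratio

    def __post_init__(self) -> None:
        if self.dog_sigma <= 0 or self.min_separation < 1 or self.t_spot <= 0:
            raise ValueError("invalid spot-detection parameters")


@dataclass
class DetectedSpot:
    center: tuple[int, int]       # (row, col) px
    peak_intensity: float
    area: float                   # px², DoG support proxy
    cell_id: int | None = None
    compartment: str = "unassigned"   # nuclear | cytoplasmic | outside


@dataclass
class SpotSet:
    spots: list[DetectedSpot]

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class ClusterSummary:
    """Connected components of N+/+ cells on the contact graph."""

    clusters: list[set[int]]
    n_clusters: int
    mean_size: float
    max_size: int
    frac_in_multi: float          # fraction of N+/+ cells in clusters ≥ 2


@dataclass
class NotchResult:
    categories: dict[int, str]            # cell id → Nneg/Ncyt/Nnuc
    fractions: dict[str, float]           # category → % of retained cells
    n_outside: int = 0
    cluster_of: dict[int, int] = field(default_factory=dict)


def detect_spots(spot_channel: np.ndarray, params: SpotParams | None = None
                 ) -> SpotSet:
    """Detect bright spots with a difference-of-Gaussians band-pass.

    Local maxima of the band-pass response, at least ``min_separation``
    apart, are kept when their response exceeds ``t_spot`` robust standard
    deviations (1.4826·MAD) of the response map.  Deterministic.
    """
    from skimage.feature import peak_local_max

    params = params or SpotParams()
    chan = np.asarray(spot_channel, dtype=float)
    if chan.ndim != 2:
        raise ValueError("detect_spots expects a single 2D channel")
    band = (ndi.gaussian_filter(chan, params.dog_sigma)
            - ndi.gaussian_filter(chan, params.k * params.dog_sigma))
    mad = np.median(np.abs(band - np.median(band)))
    robust_sd = 1.4826 * mad
    if robust_sd <= 0:
        robust_sd = band.std() if band.std() > 0 else np.inf
    thr = params.t_spot * robust_sd
    if not np.isfinite(thr):
        return SpotSet([])
    peaks = peak_local_max(band, min_distance=params.min_separation,
                           threshold_abs=thr, exclude_border=False)
    support = band > 0.5 * thr
    lab, _ = ndi.label(support)
    spots = []
    for r, c in peaks:
        comp = lab[r, c]
        area = float((lab == comp).sum()) if comp else 1.0
        spots.append(DetectedSpot((int(r), int(c)), float(chan[r, c]), area))
    spots.sort(key=lambda s: s.center)
    return SpotSet(spots)


def classify_notch(spots: SpotSet, nuclei: LabelMask, cells: LabelMask
                   ) -> tuple[NotchResult, SpotSet]:
    """Assign spots to cells/compartments and classify each retained cell.

    A spot belongs to the cell containing its center; its compartment is
    nuclear iff the center lies in that cell's nucleus.  Cell rule: no
    spots → Nneg; ≥1 cytoplasmic and 0 nuclear → Ncyt; ≥1 nuclear
    (with or without cytoplasmic) → Nnuc.  Fractions are percentages of
    retained cells and sum to 100.
    """
    if nuclei.labels.shape != cells.labels.shape:
        raise ValueError("nuclei and cells masks are misaligned")
    retained = set(cells.retained)
    n_cyt: dict[int, int] = {}
    n_nuc: dict[int, int] = {}
    n_outside = 0
    for s in spots.spots:
        r, c = s.center
        cid = int(cells.labels[r, c])
        if cid == 0:
            s.cell_id, s.compartment = None, "outside"
            n_outside += 1
            continue
        s.cell_id = cid
        if int(nuclei.labels[r, c]) == cid:
            s.compartment = "nuclear"
            n_nuc[cid] = n_nuc.get(cid, 0) + 1
        else:
            s.compartment = "cytoplasmic"
            n_cyt[cid] = n_cyt.get(cid, 0) + 1
    if n_outside:
        log.debug("%d spots outside all cells excluded", n_outside)

    categories: dict[int, str] = {}
    for cid in sorted(retained):
        if n_nuc.get(cid, 0) >= 1:
            categories[cid] = "Nnuc"
        elif n_cyt.get(cid, 0) >= 1:
            categories[cid] = "Ncyt"
        else:
            categories[cid] = "Nneg"
    n = len(categories)
    fractions = {cat: (100.0 * sum(v == cat for v in categories.values()) / n
                       if n else 0.0)
                 for cat in ("Nneg", "Ncyt", "Nnuc")}
    return NotchResult(categories, fractions, n_outside), spots


def cell_adjacency(cells: LabelMask, min_shared_border: int = 3) -> nx.Graph:
    """Contact graph: cells adjacent iff ≥ ``min_shared_border`` 4-connected
    pixel pairs straddle their labels.  Includes non-retained cells, so
    border cells still provide contact context."""
    lab = cells.labels
    pairs = []
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        pairs.append(np.column_stack([lo, hi]))
    g = nx.Graph()
    g.add_nodes_from(int(v) for v in np.unique(lab) if v > 0)
    if pairs:
        allp = np.vstack(pairs)
        if len(allp):
            uniq, cnt = np.unique(allp, axis=0, return_counts=True)
            for (i, j), n in zip(uniq, cnt):
                if n >= min_shared_border:
                    g.add_edge(int(i), int(j), shared_border=int(n))
    return g


def notch_clusters(graph: nx.Graph, categories: dict[int, str]
                   ) -> ClusterSummary:
    """Connected components of the subgraph induced by N+/+ cells.

    Singletons count as clusters of size 1.  ``frac_in_multi`` is the
    fraction of N+/+ cells sitting in clusters of size ≥ 2.
    """
    nnuc = [cid for cid, cat in categories.items() if cat == "Nnuc"]
    sub = graph.subgraph(nnuc)
    comps = [set(c) for c in nx.connected_components(sub)]
    # cells labelled Nnuc but absent from the graph still form singletons
    missing = set(nnuc) - set(sub.nodes)
    comps.extend({cid} for cid in sorted(missing))
    comps.sort(key=lambda s: min(s) if s else 0)
    sizes = [len(c) for c in comps]
    total = sum(sizes)
    return ClusterSummary(
        clusters=comps,
        n_clusters=len(comps),
        mean_size=float(np.mean(sizes)) if sizes else 0.0,
        max_size=max(sizes) if sizes else 0,
        frac_in_multi=(sum(s for s in sizes if s >= 2) / total
                       if total else 0.0),
    )
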