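"""Nucleus and cell segmentation.

Nuclei come from the nuclear channel by smoothing, thresholding and a
distance-transform watershed split of touching objects.  Cells come from a
seeded watershed on the junction-marker intensity landscape: the junction
stain forms bright ridges along cell borders, which are exactly the
watershed lines when nuclei are used as seeds.  The monolayer is assumed
confluent, so cell labels partition the full frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .imaging_io import FieldImage

__all__ = ["LabelMask", "SegParams", "segment_nuclei", "segment_cells"]

log = logging.getLogger(__name__)


@dataclass
class LabelMask:
    """Integer-labeled segmentation image; 0 is background.

    ``retained`` lists the labels that enter per-cell statistics (e.g. after
    dropping frame-edge cells); pixels of non-retained labels are kept so
    adjacency and watershed geometry stay intact.
    """

    labels: np.ndarray
    kind: str                      # "nuclei" | "cells" | "junctions"
    pixel_size: float = 1.0
    retained: list[int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.retained is None:
            self.retained = [int(v) for v in np.unique(self.labels) if v > 0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class SegParams:
    smooth_sigma: float = 2.0            # px
    threshold_method: str = "otsu"       # "otsu" | "fixed"
    fixed_threshold: float = 0.0
    min_nucleus_area: float = 30.0       # µm²
    max_nucleus_area: float = 400.0      # µm²
    split_min_distance: int = 12         # px
    border_policy: str = "exclude"       # "exclude" | "keep"
    min_shared_border: int = 3           # px

    def __post_init__(self) -> None:
        if self.min_nucleus_area <= 0 or self.max_nucleus_area <= 0:
            raise ValueError("nucleus areas must be positive")
        if self.min_nucleus_area >= self.max_nucleus_area:
            raise ValueError("min_nucleus_area must be < max_nucleus_area")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")


def _relabel_by_centroid(labels: np.ndarray) -> np.ndarray:
    """Relabel to a contiguous 1..K set ordered row-major by centroid."""
    props = regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels)
    for new, p in enumerate(order, start=1):
        out[labels == p.label] = new
    return out


def segment_nuclei(fieldimg: FieldImage, params: SegParams) -> LabelMask:
    """Segment nuclei from the nuclear channel.

    Pipeline: Gaussian smooth → global threshold → fill holes → split
    touching nuclei by a watershed on the distance transform seeded at local
    maxima at least ``split_min_distance`` apart → drop components outside
    the [min, max] nucleus-area window (µm²).  Labels are sorted row-major
    by centroid for determinism.
    """
    from skimage.feature import peak_local_max

    chan = fieldimg.channel("nuclear").astype(float)
    sm = ndi.gaussian_filter(chan, params.smooth_sigma)
    if params.threshold_method == "otsu":
        if np.ptp(sm) < 1e-9:
            return LabelMask(np.zeros(sm.shape, dtype=np.int32), "nuclei",
                             fieldimg.pixel_size)
        thr = threshold_otsu(sm)
    else:
        thr = params.fixed_threshold
    binary = ndi.binary_fill_holes(sm > thr)
    if not binary.any():
        return LabelMask(np.zeros(sm.shape, dtype=np.int32), "nuclei",
                         fieldimg.pixel_size)

    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=params.split_min_distance,
                           labels=binary, exclude_border=False)
    markers = np.zeros(sm.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-dist, markers=markers, mask=binary)

    px_area = fieldimg.pixel_size ** 2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in regionprops(labels):
        area_um2 = p.area * px_area
        keep[p.label] = params.min_nucleus_area <= area_um2 <= \
            params.max_nucleus_area
    labels = np.where(keep[labels], labels, 0)
    labels = _relabel_by_centroid(labels)
    return LabelMask(labels.astype(np.int32), "nuclei", fieldimg.pixel_size)


def segment_cells(fieldimg: FieldImage, nuclei: LabelMask,
                  params: SegParams) -> LabelMask:
    """Segment cells by seeded watershed on the junction-channel landscape.

    Under the confluent assumption the foreground is the whole frame, so
    every pixel receives the label of its seed nucleus (cell id = nucleus
    id).  With ``border_policy='exclude'`` cells touching the frame edge
    are dropped from ``retained`` but their pixels stay labeled.
    """
    if nuclei.n_objects == 0:
        raise ValueError("no seeds: empty nuclei mask")
    chan = fieldimg.channel("junction").astype(float)
    sm = ndi.gaussian_filter(chan, params.smooth_sigma)
    labels = watershed(sm, markers=nuclei.labels.astype(np.int32))
    # seeds keep their own labels, but force exact nucleus-in-cell nesting
    nz = nuclei.labels > 0
    labels[nz] = nuclei.labels[nz]

    retained = [int(v) for v in np.unique(labels) if v > 0]
    if params.border_policy == "exclude":
        edge = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        edge_set = {int(v) for v in edge if v > 0}
        retained = [v for v in retained if v not in edge_set]
        log.debug("border exclusion dropped %d cells", len(edge_set))
    return LabelMask(labels.astype(np.int32), "cells", fieldimg.pixel_size,
                     retained=retained)
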