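"""Multi-channel field I/O and offset-based tile stitching.

Fields are stored as multi-page TIFF (one page per channel) with a JSON
sidecar carrying channel roles, pixel size and the tile origin.  Stitching
trusts the nominal stage offsets implied by the tile grid and overlap
fraction — no registration — and blends overlap strips by linear feathering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FieldImage", "FormatError", "read_field", "write_field",
           "stitch_area", "CHANNEL_ROLES"]

CHANNEL_ROLES = ("nuclear", "junction", "spots")


class FormatError(ValueError):
    """Raised when a field file is inconsistent with its metadata."""


@dataclass
class FieldImage:
    """One multi-channel 2D field.

    ``data`` has shape (channels, rows, cols); ``channel_roles`` names each
    page; ``pixel_size`` is in µm/px; ``origin`` is the (row, col) offset of
    this tile in area coordinates.
    """

    data: np.ndarray
    channel_roles: list[str]
    pixel_size: float = 1.0
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("field data must be (channels, rows, cols)")
        if len(self.channel_roles) != self.data.shape[0]:
            raise FormatError(
                f"{self.data.shape[0]} pages but "
                f"{len(self.channel_roles)} declared channel roles")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D channel with the given role."""
        try:
            return self.data[self.channel_roles.index(role)]
        except ValueError:
            raise KeyError(f"field has no {role!r} channel "
                           f"(roles: {self.channel_roles})") from None


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_field(fieldimg: FieldImage, path) -> None:
    """Write a field as multi-page TIFF + JSON sidecar (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, fieldimg.data, photometric="minisblack")
    meta = {"channel_roles": list(fieldimg.channel_roles),
            "pixel_size": fieldimg.pixel_size,
            "origin": list(fieldimg.origin)}
    _sidecar(path).write_text(json.dumps(meta))


def read_field(path) -> FieldImage:
    """Read a field written by :func:`write_field`; bit-exact round trip."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such field file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as e:  # noqa: BLE001 - report the offending path
        raise FormatError(f"unreadable TIFF {path}: {e}") from e
    if data.ndim == 2:
        data = data[None]
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    else:
        meta = {"channel_roles": list(CHANNEL_ROLES[: data.shape[0]]),
                "pixel_size": 1.0, "origin": [0, 0]}
    if len(meta["channel_roles"]) != data.shape[0]:
        raise FormatError(
            f"{path}: {data.shape[0]} pages but "
            f"{len(meta['channel_roles'])} declared channel roles")
    return FieldImage(data=data, channel_roles=list(meta["channel_roles"]),
                      pixel_size=float(meta["pixel_size"]),
                      origin=tuple(meta["origin"]))


def _feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Separable ramp: weight grows linearly away from each tile edge."""
    r = np.minimum(np.arange(shape[0]) + 1, np.arange(shape[0])[::-1] + 1)
    c = np.minimum(np.arange(shape[1]) + 1, np.arange(shape[1])[::-1] + 1)
    return np.minimum.outer(r, c).astype(float)


def stitch_area(tiles: list[FieldImage], grid: tuple[int, int],
                overlap_frac: float) -> FieldImage:
    """Stitch a row-major list of tiles into one area mosaic.

    Tiles are placed at nominal offsets ``step = round(dim·(1−overlap))``
    per axis; overlapping strips are blended by feathered averaging, so any
    constant-valued tile set stitches to a constant mosaic.
    """
    rows, cols = grid
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles for grid {grid}, "
                         f"got {len(tiles)}")
    if not 0 <= overlap_frac < 0.5:
        raise ValueError("overlap_frac must be in [0, 0.5)")
    shape = tiles[0].shape
    nchan = tiles[0].data.shape[0]
    for t in tiles:
        if t.shape != shape or t.data.shape[0] != nchan:
            raise ValueError("all tiles must share the same shape")
    step_r = int(round(shape[0] * (1 - overlap_frac)))
    step_c = int(round(shape[1] * (1 - overlap_frac)))
    out_shape = ((rows - 1) * step_r + shape[0],
                 (cols - 1) * step_c + shape[1])
    acc = np.zeros((nchan,) + out_shape, dtype=float)
    wsum = np.zeros(out_shape, dtype=float)
    w = _feather_weight(shape)
    for k, t in enumerate(tiles):
        i, j = divmod(k, cols)
        r0, c0 = i * step_r, j * step_c
        acc[:, r0:r0 + shape[0], c0:c0 + shape[1]] += t.data * w
        wsum[r0:r0 + shape[0], c0:c0 + shape[1]] += w
    mosaic = acc / wsum
    if np.issubdtype(tiles[0].data.dtype, np.integer):
        mosaic = np.clip(np.round(mosaic), 0,
                         np.iinfo(tiles[0].data.dtype).max
                         ).astype(tiles[0].data.dtype)
    return FieldImage(data=mosaic, channel_roles=list(tiles[0].channel_roles),
                      pixel_size=tiles[0].pixel_size)
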