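"""Image-stack and ROI input/output, montage assembly, background subtraction.

The pipeline standardizes on TIFF: stacks are stored as shaped TIFF files
with a JSON metadata block (channel names, pixel size, frame interval,
modality) written through :mod:`tifffile`, and cell ROIs come either from
label-mask TIFFs or from ImageJ ``.roi``/``.zip`` files. Missing physical
metadata is surfaced as ``None``, never silently defaulted.

The ImageJ ROI codec implemented here covers the subset of the binary
format the workflow needs (rectangle, oval, polygon, freehand); coordinates
follow ImageJ's convention of a pixel-corner origin, and rasterization uses
half-open pixel boundaries: a pixel belongs to a ROI iff its centre lies
inside the shape.
"""

from __future__ import annotations

import json
import math
import struct
import zipfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

AXES = "ptcyx"

_METADATA_KEY = "mcsquant"


class LayoutError(ValueError):
    """An axis layout string cannot be mapped onto (p, t, c, y, x)."""


class RoiError(ValueError):
    """Malformed, empty or colliding ROI definitions."""


@dataclass(frozen=True)
class ImageStack:
    """Intensity data indexed (position, time, channel, y, x) plus metadata.

    ``pixel_size_um`` and ``frame_interval_s`` are ``None`` when unknown.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    modality: str = "unknown"

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5-D (p,t,c,y,x), got {self.data.ndim}-D"
            )
        if len(self.channels) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[2]} channels"
            )

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def frame(self, position: int = 0, time: int = 0, channel: int | str = 0) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.channels.index(channel)
        return self.data[position, time, channel]

    def times_s(self) -> np.ndarray | None:
        if self.frame_interval_s is None:
            return None
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class CellROISet:
    """Integer-labelled per-cell masks on an image's (y, x) grid."""

    labels: np.ndarray
    background_label: int | None = None

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = unassigned)")

    @property
    def cell_ids(self) -> list[int]:
        ids = sorted(int(v) for v in np.unique(self.labels) if v > 0)
        if self.background_label is not None:
            ids = [i for i in ids if i != self.background_label]
        return ids

    def mask(self, cell_id: int) -> np.ndarray:
        m = self.labels == cell_id
        if not m.any():
            raise RoiError(f"cell label {cell_id} has no pixels")
        return m

    def background_mask(self) -> np.ndarray:
        if self.background_label is None:
            raise RoiError("no background label declared for this ROI set")
        m = self.labels == self.background_label
        if not m.any():
            raise RoiError(f"background label {self.background_label} has no pixels")
        return m


def _expand_layout(arr: np.ndarray, layout: str) -> np.ndarray:
    layout = layout.lower()
    for ax in layout:
        if ax not in AXES:
            raise LayoutError(f"unknown axis {ax!r} in layout {layout!r} (allowed: p,t,c,y,x)")
    if len(set(layout)) != len(layout):
        raise LayoutError(f"duplicate axis in layout {layout!r}")
    if "y" not in layout or "x" not in layout:
        raise LayoutError(f"layout {layout!r} must contain both 'y' and 'x'")
    if arr.ndim != len(layout):
        raise LayoutError(
            f"layout {layout!r} has {len(layout)} axes but the file has {arr.ndim}"
        )
    # insert singleton axes for anything missing, then order as AXES
    for ax in AXES:
        if ax not in layout:
            arr = arr[np.newaxis]
            layout = ax + layout
    return np.transpose(arr, [layout.index(ax) for ax in AXES])


def read_stack(
    path: str | Path,
    layout: str | None = None,
    channels: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    modality: str | None = None,
) -> ImageStack:
    """Read a TIFF into a validated 5-D stack.

    ``layout`` maps file axes onto (p, t, c, y, x), e.g. ``"tcyx"``; files
    written by :func:`write_stack` carry their own layout and metadata,
    which explicit arguments override.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0]).get(_METADATA_KEY, {})
    if layout is None:
        layout = meta.get("layout")
    if layout is None:
        if arr.ndim == 2:
            layout = "yx"
        else:
            raise LayoutError(
                f"{path.name}: no layout stored in file; pass layout= for a {arr.ndim}-D array"
            )
    data = _expand_layout(arr, layout)
    if channels is None:
        channels = meta.get("channels")
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[2]))
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um")
    if frame_interval_s is None:
        frame_interval_s = meta.get("frame_interval_s")
    if modality is None:
        modality = meta.get("modality", "unknown")
    return ImageStack(
        data=data,
        channels=tuple(channels),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        modality=modality,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as shaped TIFF with a JSON metadata block (lossless)."""
    meta = {
        _METADATA_KEY: {
            "layout": AXES,
            "channels": list(stack.channels),
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
            "modality": stack.modality,
        }
    }
    tifffile.imwrite(Path(path), stack.data, metadata=meta, photometric="minisblack")


def stack_from_channels(
    channels: dict[str, np.ndarray],
    pixel_size_um: float | None = None,
    modality: str = "unknown",
) -> ImageStack:
    """Pack single-frame 2-D channel images into a (1,1,C,Y,X) stack."""
    names = tuple(channels)
    data = np.stack([np.asarray(channels[n], dtype=float) for n in names])
    return ImageStack(
        data=data[np.newaxis, np.newaxis],
        channels=names,
        pixel_size_um=pixel_size_um,
        modality=modality,
    )


def assemble_montage(
    stacks: Sequence[ImageStack],
) -> tuple[ImageStack, pd.DataFrame]:
    """Tile per-position stacks into one montage, row-major on a near-square grid.

    Returns the montage (a single-position stack) and an offset table with
    one row per input position, so montage-space ROI coordinates can be
    mapped back to their source position.
    """
    if not stacks:
        raise ValueError("no stacks to assemble")
    first = stacks[0]
    for i, s in enumerate(stacks):
        if s.data.shape[1:] != first.data.shape[1:] or s.channels != first.channels:
            raise ValueError(
                f"position {i} shape {s.data.shape[1:]}/channels {s.channels} do not "
                f"match position 0 ({first.data.shape[1:]}, {first.channels})"
            )
        if s.n_positions != 1:
            raise ValueError(f"input stack {i} must be single-position")
    n = len(stacks)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    t, c, h, w = first.data.shape[1:]
    canvas = np.zeros((1, t, c, nrows * h, ncols * w), dtype=first.data.dtype)
    rows = []
    for i, s in enumerate(stacks):
        r, col = divmod(i, ncols)
        y0, x0 = r * h, col * w
        canvas[0, :, :, y0 : y0 + h, x0 : x0 + w] = s.data[0]
        rows.append({"position": i, "y_offset": y0, "x_offset": x0})
    montage = replace(first, data=canvas)
    return montage, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ImageJ ROI binary format (subset)

_ROI_MAGIC = b"Iout"
_ROI_TYPES = {"polygon": 0, "rectangle": 1, "oval": 2, "freehand": 7}
_ROI_TYPE_NAMES = {v: k for k, v in _ROI_TYPES.items()}


def encode_imagej_roi(
    kind: str,
    *,
    top: int = 0,
    left: int = 0,
    bottom: int = 0,
    right: int = 0,
    points: Sequence[tuple[float, float]] | None = None,
) -> bytes:
    """Encode one ROI in the ImageJ binary format.

    For ``rectangle``/``oval`` pass the bounding box (half-open: a
    rectangle covering pixels rows ``top..bottom-1``); for ``polygon``/
    ``freehand`` pass vertices as (x, y) in pixel-corner coordinates.
    """
    if kind not in _ROI_TYPES:
        raise RoiError(f"unsupported ROI kind {kind!r}")
    n = 0
    coord_block = b""
    if kind in ("polygon", "freehand"):
        if not points or len(points) < 3:
            raise RoiError("polygon ROI needs at least 3 vertices")
        xs = [int(round(x)) for x, _ in points]
        ys = [int(round(y)) for _, y in points]
        left, top = min(xs), min(ys)
        right, bottom = max(xs), max(ys)
        n = len(points)
        rel = [x - left for x in xs] + [y - top for y in ys]
        coord_block = struct.pack(f">{2 * n}h", *rel)
    header = struct.pack(
        ">4shBBhhhhh46x",
        _ROI_MAGIC,
        227,  # version
        _ROI_TYPES[kind],
        0,
        top,
        left,
        bottom,
        right,
        n,
    )
    assert len(header) == 64
    return header + coord_block


def decode_imagej_roi(data: bytes) -> tuple[str, dict]:
    """Decode one ImageJ ROI; returns (kind, geometry dict)."""
    if len(data) < 64 or data[:4] != _ROI_MAGIC:
        raise RoiError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    if roi_type not in _ROI_TYPE_NAMES:
        raise RoiError(f"unsupported ImageJ ROI type code {roi_type}")
    kind = _ROI_TYPE_NAMES[roi_type]
    top, left, bottom, right, n = struct.unpack(">hhhhh", data[8:18])
    geom: dict = {"top": top, "left": left, "bottom": bottom, "right": right}
    if kind in ("polygon", "freehand"):
        rel = struct.unpack(f">{2 * n}h", data[64 : 64 + 4 * n])
        xs = [left + v for v in rel[:n]]
        ys = [top + v for v in rel[n:]]
        geom["points"] = list(zip(xs, ys))
    return kind, geom


def _rasterize(kind: str, geom: dict, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "rectangle":
        return (
            (yy >= geom["top"]) & (yy < geom["bottom"]) & (xx >= geom["left"]) & (xx < geom["right"])
        )
    if kind == "oval":
        a = (geom["right"] - geom["left"]) / 2.0
        b = (geom["bottom"] - geom["top"]) / 2.0
        if a <= 0 or b <= 0:
            raise RoiError("oval ROI has an empty bounding box")
        cx = geom["left"] + a
        cy = geom["top"] + b
        return ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2 <= 1.0
    # polygon / freehand: pixel centres inside the polygon
    poly = Polygon(geom["points"])
    if not poly.is_valid or poly.area == 0:
        raise RoiError("polygon ROI is degenerate (zero area or self-intersecting)")
    inside = shapely.contains_xy(poly, (xx + 0.5).ravel(), (yy + 0.5).ravel())
    return inside.reshape(shape)


def load_rois(
    path: str | Path,
    shape: tuple[int, int] | None = None,
    background_label: int | None = None,
) -> CellROISet:
    """Load cell ROIs from a label-mask TIFF or ImageJ .roi/.zip file.

    ImageJ ROIs are rasterized to labels 1..n in file order; overlapping
    ROIs are an explicit failure (no silent precedence).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise RoiError(f"label-mask TIFF must be 2-D, got {arr.ndim}-D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise RoiError("label-mask TIFF must contain integer labels")
        return CellROISet(labels=arr.astype(np.int32), background_label=background_label)
    if shape is None:
        raise RoiError("shape is required to rasterize ImageJ ROI files")
    if suffix == ".roi":
        blobs = [path.read_bytes()]
    elif suffix == ".zip":
        with zipfile.ZipFile(path) as zf:
            blobs = [zf.read(n) for n in zf.namelist() if n.lower().endswith(".roi")]
        if not blobs:
            raise RoiError(f"{path.name} contains no .roi entries")
    else:
        raise RoiError(f"unsupported ROI file type {suffix!r}")
    labels = np.zeros(shape, dtype=np.int32)
    for i, blob in enumerate(blobs, start=1):
        kind, geom = decode_imagej_roi(blob)
        mask = _rasterize(kind, geom, shape)
        if not mask.any():
            raise RoiError(f"ROI #{i} rasterizes to zero pixels")
        clash = mask & (labels > 0)
        if clash.any():
            raise RoiError(
                f"ROI #{i} overlaps ROI #{int(labels[clash][0])} "
                f"on {int(clash.sum())} pixels"
            )
        labels[mask] = i
    return CellROISet(labels=labels, background_label=background_label)


def save_label_mask(rois: CellROISet, path: str | Path) -> None:
    tifffile.imwrite(Path(path), rois.labels.astype(np.int32), photometric="minisblack")


# --------------------------------------------------------------------------
# Background subtraction


def background_subtract(
    stack: ImageStack,
    method: str = "background-roi",
    rois: CellROISet | None = None,
    percentile: float = 1.0,
    clip: bool = True,
) -> tuple[ImageStack, pd.DataFrame]:
    """Subtract a per-frame, per-channel background scalar.

    ``background-roi`` uses the mean over the ROI set's declared
    cell-free background region; ``percentile`` uses a low in-frame
    percentile (default 1st). Negative results are clipped to 0 and every
    subtracted scalar is returned in the log table.
    """
    if method == "background-roi":
        if rois is None or rois.background_label is None:
            raise RoiError(
                "background-roi subtraction needs a CellROISet with a background label"
            )
        bg_mask = rois.background_mask()
        if bg_mask.shape != stack.frame_shape:
            raise ValueError(
                f"background mask shape {bg_mask.shape} does not match frames {stack.frame_shape}"
            )
    elif method == "percentile":
        bg_mask = None
    else:
        raise ValueError(f"unknown background method {method!r}")
    data = stack.data.astype(float).copy()
    rows = []
    for p in range(data.shape[0]):
        for t in range(data.shape[1]):
            for c in range(data.shape[2]):
                frame = data[p, t, c]
                if bg_mask is not None:
                    scalar = float(frame[bg_mask].mean())
                else:
                    scalar = float(np.percentile(frame, percentile))
                frame -= scalar
                if clip:
                    np.clip(frame, 0.0, None, out=frame)
                rows.append(
                    {"position": p, "time": t, "channel": stack.channels[c], "subtracted": scalar}
                )
    return replace(stack, data=data), pd.DataFrame(rows)
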