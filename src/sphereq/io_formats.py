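"""Reading and writing of every external artifact the pipeline touches.

Images are multi-plane grayscale TIFFs (8- or 16-bit), one plane per stain
channel; channel identity is given by the user as an ordered label list, never
taken from TIFF metadata.  Regions of interest travel in a plain-text polygon
format so manual review decisions are diffable.  Tabular results are RFC-4180
CSV with a leading ``#`` comment line documenting the column order.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image
from skimage.draw import polygon as draw_polygon

__all__ = [
    "ChannelImage",
    "ImageStack",
    "RoiEntry",
    "RoiFile",
    "read_stack",
    "write_stack",
    "read_roi_file",
    "write_roi_file",
    "write_summary_csv",
    "read_summary_csv",
    "write_nucleus_csv",
    "write_qc_overlay",
]

_DTYPE_MAX = {np.dtype(np.uint8): 255, np.dtype(np.uint16): 65535}


def _fmt(x) -> str:
    """Plain-decimal rendering that round-trips floats exactly."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return np.format_float_positional(float(x), unique=True, trim="0")
    return str(x)


@dataclass
class ChannelImage:
    """A single 2-D grayscale plane.

    ``dtype_max`` records the maximum representable source intensity (255 for
    8-bit, 65535 for 16-bit); intensities are arbitrary units ("a.u.").
    """

    pixels: np.ndarray
    dtype_max: int
    channel_label: str
    pixel_units: str = "a.u."

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ChannelImage requires a non-empty 2-D plane")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.dtype_max
        ):
            raise ValueError("intensities must lie in [0, dtype_max]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """Ordered collection of equally shaped channels with unique labels."""

    channels: list[ChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")
        labels = [c.channel_label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels: {labels}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def labels(self) -> list[str]:
        return [c.channel_label for c in self.channels]

    def channel(self, label: str) -> ChannelImage:
        for c in self.channels:
            if c.channel_label == label:
                return c
        raise KeyError(f"no channel labeled {label!r}; have {self.labels}")

    def __len__(self) -> int:
        return len(self.channels)


@dataclass
class RoiEntry:
    roi_id: str
    vertices: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    include: bool = True


@dataclass
class RoiFile:
    entries: list[RoiEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.roi_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate roi_ids: {ids}")


def read_stack(path, channel_labels: Sequence[str]) -> ImageStack:
    """Read a multi-plane TIFF, attaching the given labels in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a stack of 2-D planes, got shape {arr.shape}")
    if len(channel_labels) != arr.shape[0]:
        raise ValueError(
            f"{path.name}: {arr.shape[0]} plane(s) but {len(channel_labels)} "
            f"channel label(s) supplied"
        )
    if arr.dtype not in _DTYPE_MAX:
        raise ValueError(f"unsupported TIFF dtype {arr.dtype}; use uint8 or uint16")
    dtype_max = _DTYPE_MAX[arr.dtype]
    return ImageStack(
        channels=[
            ChannelImage(pixels=arr[i], dtype_max=dtype_max, channel_label=lab)
            for i, lab in enumerate(channel_labels)
        ]
    )


def write_stack(stack: ImageStack, path) -> Path:
    """Write channels as a multi-plane TIFF (bit-exact round trip with read_stack)."""
    path = Path(path)
    dtype = np.uint8 if stack.channels[0].dtype_max == 255 else np.uint16
    arr = np.stack([c.pixels.astype(dtype) for c in stack.channels])
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# ROI polygon files
# ---------------------------------------------------------------------------

_ROI_HEADER = "# sphereq ROI polygons v1: roi_id,include,row:col row:col ..."


def write_roi_file(rois: RoiFile, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_ROI_HEADER + "\n")
        w = csv.writer(fh)
        for e in rois.entries:
            verts = " ".join(f"{_fmt(r)}:{_fmt(c)}" for r, c in e.vertices)
            w.writerow([e.roi_id, int(e.include), verts])
    return path


def parse_roi_file(path) -> RoiFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    entries = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    for row in rows:
        if len(row) != 3:
            raise ValueError(f"malformed ROI line {row!r}: expected 3 fields")
        roi_id, include, verts = row
        try:
            pts = np.array(
                [[float(p) for p in v.split(":")] for v in verts.split()], dtype=float
            )
        except ValueError as exc:
            raise ValueError(f"ROI {roi_id!r}: unparseable vertex list") from exc
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError(f"ROI {roi_id!r}: a polygon needs >= 3 row:col vertices")
        entries.append(RoiEntry(roi_id=roi_id, vertices=pts, include=include == "1"))
    return RoiFile(entries=entries)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the polygon at the given image shape (center-inside rule)."""
    v = np.asarray(vertices, dtype=float)
    if (v < -0.5).any() or (v[:, 0] > shape[0] - 0.5).any() or (v[:, 1] > shape[1] - 0.5).any():
        raise ValueError(
            f"polygon vertex outside image bounds {shape}: "
            f"rows [{v[:, 0].min()}, {v[:, 0].max()}], cols [{v[:, 1].min()}, {v[:, 1].max()}]"
        )
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def read_roi_file(path, shape: tuple[int, int]) -> list[tuple[str, np.ndarray]]:
    """Parse a ROI polygon file and rasterize the included entries.

    Entries flagged ``include=0`` (the recorded manual-review exclusions) are
    dropped.  Returns ``(roi_id, mask)`` pairs in file order.
    """
    rois = parse_roi_file(path)
    out = []
    for e in rois.entries:
        if not e.include:
            continue
        out.append((e.roi_id, rasterize_polygon(e.vertices, shape)))
    return out


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _summary_columns(rows) -> tuple[list[str], list[str]]:
    combos: list[str] = []
    for s in rows:
        for k in s.n_positive:
            if k not in combos:
                combos.append(k)
    cols = ["image_id", "roi_id", "n_nuclei"]
    cols += [f"count:{c}" for c in combos] + [f"prop:{c}" for c in combos]
    return cols, combos


def write_summary_csv(rows, path) -> Path:
    """Write per-neurosphere summaries; one row per summary, counts explicit.

    Proportions of an empty neurosphere (``n_nuclei == 0``) are written as
    ``NA`` rather than a number.
    """
    path = Path(path)
    cols, combos = _summary_columns(rows)
    with open(path, "w", newline="") as fh:
        fh.write("# columns: " + ",".join(cols) + "\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for s in rows:
            rec = [s.image_id, s.roi_id, s.n_nuclei]
            rec += [_fmt(s.n_positive.get(c, 0)) for c in combos]
            rec += [
                "NA" if s.proportion.get(c) is None else _fmt(s.proportion.get(c, 0.0))
                for c in combos
            ]
            w.writerow(rec)
    return path


def read_summary_csv(path):
    """Re-parse a summary CSV into plain dict rows (numbers as written)."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(io.StringIO("".join(lines)))
    out = []
    for row in reader:
        parsed = {}
        for k, v in row.items():
            if k in ("image_id",):
                parsed[k] = v
            elif v == "NA":
                parsed[k] = None
            elif k in ("roi_id", "n_nuclei") or k.startswith("count:"):
                parsed[k] = int(v)
            else:
                parsed[k] = float(v)
        out.append(parsed)
    return out


def write_nucleus_csv(records, path, image_id="") -> Path:
    """One row per nucleus: geometry, per-channel means, per-marker flags.

    ``image_id`` is a single id for all records or a sequence, one per record.
    """
    path = Path(path)
    if isinstance(image_id, str):
        image_ids = [image_id] * len(records)
    else:
        image_ids = list(image_id)
        if len(image_ids) != len(records):
            raise ValueError("image_id sequence length must match records")
    chans: list[str] = []
    marks: list[str] = []
    for r in records:
        for c in r.mean_intensity:
            if c not in chans:
                chans.append(c)
        for m in r.positive:
            if m not in marks:
                marks.append(m)
    cols = ["image_id", "roi_id", "nucleus_id", "area", "centroid_row", "centroid_col"]
    cols += [f"mean:{c}" for c in chans] + [f"pos:{m}" for m in marks]
    with open(path, "w", newline="") as fh:
        fh.write("# columns: " + ",".join(cols) + "\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for img_id, r in zip(image_ids, records):
            rec = [img_id, r.roi_id, r.nucleus_id, _fmt(r.area),
                   _fmt(r.centroid[0]), _fmt(r.centroid[1])]
            rec += [_fmt(r.mean_intensity.get(c, "")) for c in chans]
            rec += [int(bool(r.positive[m])) if m in r.positive else "" for m in marks]
            w.writerow(rec)
    return path


# ---------------------------------------------------------------------------
# QC overlays
# ---------------------------------------------------------------------------

_ROI_COLOR = (255, 255, 0)
_CLASS_PALETTE = [
    (0, 255, 0), (255, 0, 0), (0, 128, 255), (255, 0, 255),
    (0, 255, 255), (255, 128, 0), (128, 255, 0), (128, 0, 255),
]
_NEGATIVE_COLOR = (160, 160, 160)


def _outline(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi

    er = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return mask & ~er


def write_qc_overlay(stack: ImageStack, rois, nuclei, path, base_channel: str | None = None) -> Path:
    """Write an RGB overlay: base channel gray, ROI outlines yellow, nucleus
    outlines colored by positivity class.  Deterministic for fixed inputs and
    never mutates the stack.
    """
    path = Path(path)
    base = stack.channel(base_channel) if base_channel else stack.channels[0]
    gray = (base.pixels.astype(np.float64) * (255.0 / base.dtype_max)).round()
    rgb = np.repeat(gray.astype(np.uint8)[:, :, None], 3, axis=2)
    shape = stack.shape
    for roi in rois:
        if roi.mask.shape != shape:
            raise ValueError(f"ROI {roi.roi_id} mask shape {roi.mask.shape} != {shape}")
        rgb[_outline(roi.mask)] = _ROI_COLOR
    classes = sorted(
        {tuple(sorted(m for m, p in n.positive.items() if p)) for n in nuclei}
    )
    for n in nuclei:
        r, c = n.centroid
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"nucleus {n.nucleus_id} centroid {n.centroid} outside {shape}")
        key = tuple(sorted(m for m, p in n.positive.items() if p))
        color = (
            _NEGATIVE_COLOR
            if not key
            else _CLASS_PALETTE[classes.index(key) % len(_CLASS_PALETTE)]
        )
        rad = max(2.0, float(np.sqrt(n.area / np.pi)) + 1.0)
        r0 = max(0, int(r - rad) - 2)
        r1 = min(shape[0], int(r + rad) + 3)
        c0 = max(0, int(c - rad) - 2)
        c1 = min(shape[1], int(c + rad) + 3)
        rr, cc = np.ogrid[r0:r1, c0:c1]
        d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
        ring = (d >= rad - 0.7) & (d <= rad + 0.7)
        rgb[r0:r1, c0:c1][ring] = color
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path
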