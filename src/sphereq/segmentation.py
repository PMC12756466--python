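"""The two segmentation stages: neurosphere ROI detection on the pan-neuronal
(HU) channel, and nucleus isolation on the DAPI channel within each ROI.

Both compose the preprocessing primitives and end in particle gating on area
and circularity, mirroring the two analysis macros: neurospheres are kept at
1,000-50,000 px² and circularity 0.5-1.0, nuclei at 10-1,000 px² and
circularity 0.3-1.0 (all bounds inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io_formats import ChannelImage
from .preprocessing import (
    PreprocessParams,
    invert,
    median_filter,
    morphological_clean,
    subtract_background_rolling,
    threshold_window,
    to_8bit,
    watershed_split,
)

__all__ = [
    "ParticleGate",
    "RegionOfInterest",
    "region_perimeter",
    "find_particles",
    "segment_neurospheres",
    "segment_nuclei_in_roi",
    "manual_rois_from_file",
    "NEUROSPHERE_GATE",
    "NUCLEUS_GATE",
]


@dataclass
class ParticleGate:
    """Inclusive area (px²) and circularity bounds for particle retention."""

    area_min: float = 10.0
    area_max: float = 1000.0
    circ_min: float = 0.3
    circ_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.area_min <= self.area_max:
            raise ValueError("gate requires 0 <= area_min <= area_max")
        if not 0 <= self.circ_min <= self.circ_max <= 1:
            raise ValueError("gate requires 0 <= circ_min <= circ_max <= 1")

    def admits(self, area: float, circularity: float) -> bool:
        return (
            self.area_min <= area <= self.area_max
            and self.circ_min <= circularity <= self.circ_max
        )


NEUROSPHERE_GATE = ParticleGate(1000.0, 50000.0, 0.5, 1.0)
NUCLEUS_GATE = ParticleGate(10.0, 1000.0, 0.3, 1.0)


@dataclass
class RegionOfInterest:
    """A labeled pixel region used both for neurospheres and nuclei.

    ``circularity`` is 4π·area/perimeter², capped at 1.0; the perimeter is the
    Crofton estimate (4 directions), which is unbiased on rasterized disks
    where raw pixel-edge counting would deflate circularity by ~20%.
    """

    roi_id: int
    mask: np.ndarray
    area: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    source: str = "auto"


def region_perimeter(mask: np.ndarray) -> float:
    """Crofton perimeter (4 directions) of a boolean region mask."""
    return float(measure.perimeter_crofton(np.asarray(mask, bool), directions=4))


def _roi_from_mask(mask: np.ndarray, roi_id: int, source: str) -> RegionOfInterest:
    area = float(mask.sum())
    if area == 0:
        raise ValueError("cannot build a ROI from an empty mask")
    rows, cols = np.nonzero(mask)
    perim = region_perimeter(mask)
    circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
    return RegionOfInterest(
        roi_id=roi_id,
        mask=mask,
        area=area,
        perimeter=perim,
        circularity=circ,
        centroid=(float(rows.mean()), float(cols.mean())),
        bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
        source=source,
    )


def find_particles(labels: np.ndarray, gate: ParticleGate) -> list[RegionOfInterest]:
    """One ROI per label passing the gate, ordered by label.

    Retained ROIs keep their ordinal position (1-based re-numbering in label
    order); label gaps from gated-out particles are documented behavior.
    """
    out: list[RegionOfInterest] = []
    objects = ndi.find_objects(labels)
    next_id = 1
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        area = float(sub.sum())
        perim = region_perimeter(sub)
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        if not gate.admits(area, circ):
            continue
        mask = np.zeros(labels.shape, dtype=bool)
        mask[sl] = sub
        roi = _roi_from_mask(mask, next_id, "auto")
        out.append(roi)
        next_id += 1
    return out


def segment_neurospheres(
    hu: ChannelImage,
    params: PreprocessParams | None = None,
    gate: ParticleGate = NEUROSPHERE_GATE,
) -> list[RegionOfInterest]:
    """Detect neurosphere ROIs on the pan-neuronal channel.

    Pipeline: 8-bit conversion -> inversion -> inclusive threshold window ->
    morphological closing/opening -> distance-transform watershed -> particle
    gate (defaults 1,000-50,000 px², circularity 0.5-1.0).
    """
    if params is None:
        params = PreprocessParams(
            invert=True, threshold_lo=0, threshold_hi=200,
            morph_radius=25, watershed_min_distance=50,
        )
    img = to_8bit(hu)
    if params.invert:
        img = invert(img)
    mask = threshold_window(img, params.threshold_lo, params.threshold_hi)
    if params.window_selects == "background":
        mask = ~mask
    mask = morphological_clean(mask, params.morph_radius)
    labels = watershed_split(mask, params.watershed_min_distance)
    return find_particles(labels, gate)


def _nucleus_mask_stage(img: ChannelImage, params: PreprocessParams) -> np.ndarray:
    """Shared DAPI-style conditioning: top-hat background removal, polarity,
    inclusive window, binary median despeckling."""
    img = to_8bit(img)
    img = subtract_background_rolling(img, params.rolling_radius)
    if params.invert:
        img = invert(img)
    mask = threshold_window(img, params.threshold_lo, params.threshold_hi)
    if params.window_selects == "background":
        mask = ~mask
    as_img = ChannelImage(
        pixels=(mask.astype(np.uint8) * 255), dtype_max=255, channel_label="mask"
    )
    mask = median_filter(as_img, params.median_radius).pixels > 127
    return mask


def segment_nuclei_in_roi(
    dapi: ChannelImage,
    roi: RegionOfInterest,
    params: PreprocessParams | None = None,
    gate: ParticleGate = NUCLEUS_GATE,
) -> list[RegionOfInterest]:
    """Isolate nuclei on the DAPI channel within one neurosphere ROI.

    Pipeline: 8-bit -> rolling background subtraction (30 px) -> threshold
    (window 0-13 a.u. marking residual background; foreground is its
    complement) -> median filter (1 px) -> watershed -> particle gate
    (10-1,000 px², circularity 0.3-1.0).  A nucleus belongs to the ROI iff its
    centroid falls inside ``roi.mask``; segmentation runs on a margin-expanded
    bounding box so nuclei straddling the ROI edge keep their true geometry.
    """
    if params is None:
        params = PreprocessParams(
            rolling_radius=30, threshold_lo=0, threshold_hi=13,
            window_selects="background", median_radius=1, watershed_min_distance=5,
        )
    if roi.mask.shape != dapi.shape:
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} does not match image {dapi.shape}"
        )
    margin = 3 * params.rolling_radius
    r0 = max(0, roi.bbox[0] - margin)
    c0 = max(0, roi.bbox[1] - margin)
    r1 = min(dapi.shape[0], roi.bbox[2] + margin)
    c1 = min(dapi.shape[1], roi.bbox[3] + margin)
    window = ChannelImage(
        pixels=dapi.pixels[r0:r1, c0:c1],
        dtype_max=dapi.dtype_max,
        channel_label=dapi.channel_label,
    )
    mask = _nucleus_mask_stage(window, params)
    labels = watershed_split(mask, params.watershed_min_distance)
    nuclei = []
    next_id = 1
    for part in find_particles(labels, gate):
        cr, cc = part.centroid
        rr, rc = int(round(cr)) + r0, int(round(cc)) + c0
        if not (0 <= rr < dapi.shape[0] and 0 <= rc < dapi.shape[1]):
            continue
        if not roi.mask[rr, rc]:
            continue
        full = np.zeros(dapi.shape, dtype=bool)
        full[r0:r1, c0:c1] = part.mask
        nuc = _roi_from_mask(full, next_id, "auto")
        nuclei.append(nuc)
        next_id += 1
    return nuclei


def manual_rois_from_file(roi_pairs, shape=None) -> list[RegionOfInterest]:
    """Wrap rasterized manual polygons as trusted ROIs (no gate applied).

    ``roi_pairs`` is the ``(roi_id, mask)`` list from
    :func:`sphereq.io_formats.read_roi_file`.
    """
    out = []
    for i, (_, mask) in enumerate(roi_pairs, start=1):
        out.append(_roi_from_mask(mask, i, "manual"))
    return out
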