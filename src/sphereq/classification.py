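"""Per-nucleus marker-intensity measurement and thresholded positivity calls.

A nucleus is positive for a marker when its mean intensity over the nucleus
mask strictly exceeds the marker's threshold (">10 a.u." semantics; defaults:
10 a.u. for the green and far-red channels and for HU, 30 a.u. for red).
Marker channels are background-subtracted (rolling = 30 px) and converted to
8-bit before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ChannelImage, ImageStack
from .preprocessing import subtract_background_rolling, to_8bit
from .segmentation import RegionOfInterest

__all__ = [
    "NucleusRecord",
    "MarkerThresholds",
    "measure_nucleus_intensity",
    "classify_positivity",
    "classify_stack",
    "DEFAULT_THRESHOLDS",
]


@dataclass
class MarkerThresholds:
    """Map marker label -> positivity threshold in 8-bit a.u."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {"HU": 10.0, "green": 10.0, "far-red": 10.0, "red": 30.0}
    )

    def __post_init__(self) -> None:
        for m, t in self.thresholds.items():
            if not 0 <= t <= 255:
                raise ValueError(f"threshold for {m!r} must be in [0, 255], got {t}")

    def items(self):
        return self.thresholds.items()


DEFAULT_THRESHOLDS = MarkerThresholds()


@dataclass
class NucleusRecord:
    """One segmented nucleus with its geometry, per-channel mean intensities,
    and per-marker positivity flags."""

    nucleus_id: int
    roi_id: int
    area: float
    centroid: tuple[float, float]
    mean_intensity: dict[str, float] = field(default_factory=dict)
    positive: dict[str, bool] = field(default_factory=dict)


def measure_nucleus_intensity(nucleus: RegionOfInterest, channel: ChannelImage) -> float:
    """Arithmetic mean of channel intensities over the nucleus mask."""
    if nucleus.mask.shape != channel.shape:
        raise ValueError(
            f"nucleus mask shape {nucleus.mask.shape} != channel shape {channel.shape}"
        )
    n = int(nucleus.mask.sum())
    if n == 0:
        raise ValueError(f"nucleus {nucleus.roi_id} has an empty mask")
    return float(channel.pixels[nucleus.mask].astype(np.float64).mean())


def classify_positivity(record: NucleusRecord, thresholds: MarkerThresholds) -> NucleusRecord:
    """Fill ``positive[m] = mean_intensity[m] > thresholds[m]`` (strict)."""
    pos = {}
    for marker, thr in thresholds.items():
        if marker not in record.mean_intensity:
            raise KeyError(
                f"nucleus {record.nucleus_id}: no measured intensity for marker "
                f"{marker!r}; have {sorted(record.mean_intensity)}"
            )
        pos[marker] = record.mean_intensity[marker] > thr
    return NucleusRecord(
        nucleus_id=record.nucleus_id,
        roi_id=record.roi_id,
        area=record.area,
        centroid=record.centroid,
        mean_intensity=dict(record.mean_intensity),
        positive=pos,
    )


def _assign_roi(nucleus: RegionOfInterest, rois: list[RegionOfInterest]) -> int:
    r, c = (int(round(x)) for x in nucleus.centroid)
    for roi in rois:
        if 0 <= r < roi.mask.shape[0] and 0 <= c < roi.mask.shape[1] and roi.mask[r, c]:
            return roi.roi_id
    return 0  # outside every neurosphere


def classify_stack(
    stack: ImageStack,
    rois: list[RegionOfInterest],
    nuclei: list[RegionOfInterest],
    thresholds: MarkerThresholds = DEFAULT_THRESHOLDS,
    rolling_radius: int = 30,
    subtract_marker_background: bool = True,
) -> list[NucleusRecord]:
    """Measure and classify every nucleus against every marker channel.

    Each marker channel named in ``thresholds`` is 8-bit-converted and (by
    default) background-subtracted once, then each nucleus's mean intensity is
    measured on it and thresholded.  Records are returned in nucleus order,
    carrying the ROI assignment by the centroid-inside rule.
    """
    missing = [m for m, _ in thresholds.items() if m not in stack.labels]
    if missing:
        raise KeyError(
            f"thresholds name channel(s) {missing} absent from stack {stack.labels}"
        )
    prepared: dict[str, ChannelImage] = {}
    for marker, _ in thresholds.items():
        ch = to_8bit(stack.channel(marker))
        if subtract_marker_background:
            ch = subtract_background_rolling(ch, rolling_radius)
        prepared[marker] = ch
    records = []
    for i, nuc in enumerate(nuclei, start=1):
        rec = NucleusRecord(
            nucleus_id=i,
            roi_id=_assign_roi(nuc, rois),
            area=nuc.area,
            centroid=nuc.centroid,
            mean_intensity={
                m: measure_nucleus_intensity(nuc, ch) for m, ch in prepared.items()
            },
        )
        records.append(classify_positivity(rec, thresholds))
    return records
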