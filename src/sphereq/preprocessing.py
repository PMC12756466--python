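"""Image-conditioning primitives shared by the segmentation stages.

All operations work on :class:`~sphereq.io_formats.ChannelImage` planes (or, for
the binary operations, on boolean masks) and mirror the conventions of common
particle-analysis macros: intensities are 8-bit arbitrary units after
conversion, thresholds are inclusive windows, and touching objects are split by
watershed on the negated Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io_formats import ChannelImage

__all__ = [
    "PreprocessParams",
    "to_8bit",
    "invert",
    "subtract_background_rolling",
    "median_filter",
    "threshold_window",
    "morphological_clean",
    "watershed_split",
    "label_components",
]


@dataclass
class PreprocessParams:
    """Parameters of one preprocessing stage.

    Attributes
    ----------
    invert:
        Invert the 8-bit image before thresholding (used by the neuron-marker
        neurosphere stage, whose macro inverts the image first).
    rolling_radius:
        Radius in px of the rolling background estimator (grayscale opening
        with a disk of this radius).
    median_radius:
        Radius in px of the median despeckling filter applied to the
        thresholded mask.
    threshold_lo, threshold_hi:
        Inclusive intensity window in 8-bit a.u.
    window_selects:
        Whether the window marks ``"foreground"`` (the mask is the window) or
        ``"background"`` (the mask is its complement).  The nucleus stage
        thresholds a background-subtracted image at 0-13 a.u. to delimit the
        residual background, so its foreground is the complement.
    morph_radius:
        Disk radius in px of the binary closing-then-opening clean-up.
    watershed_min_distance:
        Minimum separation in px between watershed seed maxima.
    """

    invert: bool = False
    rolling_radius: int = 30
    median_radius: int = 1
    threshold_lo: float = 0.0
    threshold_hi: float = 13.0
    window_selects: str = "foreground"
    morph_radius: int = 25
    watershed_min_distance: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_lo <= self.threshold_hi <= 255:
            raise ValueError(
                "threshold window must satisfy 0 <= lo <= hi <= 255, got "
                f"[{self.threshold_lo}, {self.threshold_hi}]"
            )
        for name in ("rolling_radius", "median_radius", "morph_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.window_selects not in ("foreground", "background"):
            raise ValueError("window_selects must be 'foreground' or 'background'")


def _disk_footprint(radius: int, decompose: bool = False):
    if decompose:
        # Sequence decomposition: large-radius openings in ~linear time with
        # <=1 a.u. deviation from the exact disk element.
        return morphology.disk(radius, decomposition="sequence")
    return morphology.disk(radius)


def to_8bit(img: ChannelImage) -> ChannelImage:
    """Linearly rescale ``[0, dtype_max]`` onto ``[0, 255]`` (round half up).

    8-bit input is returned unchanged (idempotent).
    """
    if img.dtype_max == 255:
        return img
    scaled = np.floor(img.pixels.astype(np.float64) * (255.0 / img.dtype_max) + 0.5)
    pixels = np.clip(scaled, 0, 255).astype(np.uint8)
    return ChannelImage(pixels=pixels, dtype_max=255, channel_label=img.channel_label)


def invert(img: ChannelImage) -> ChannelImage:
    """Map every pixel p to 255 - p.  Involution on 8-bit images."""
    if img.dtype_max != 255:
        raise ValueError("invert requires an 8-bit image; call to_8bit first")
    return ChannelImage(
        pixels=(255 - img.pixels.astype(np.int16)).astype(np.uint8),
        dtype_max=255,
        channel_label=img.channel_label,
    )


def subtract_background_rolling(img: ChannelImage, radius: int = 30) -> ChannelImage:
    """Remove smooth background estimated by grayscale opening (disk of ``radius``).

    The result is the white top-hat of the image: anti-extensive (never exceeds
    the input), zero on any structure wider than the element, and preserves
    compact bright objects smaller than the element.
    """
    if radius < 1:
        raise ValueError("rolling radius must be >= 1")
    if img.dtype_max != 255:
        raise ValueError("subtract_background_rolling requires an 8-bit image")
    fp = _disk_footprint(radius, decompose=True)
    background = morphology.opening(img.pixels, footprint=fp)
    out = (img.pixels.astype(np.int16) - background.astype(np.int16)).clip(0, 255)
    return ChannelImage(
        pixels=out.astype(np.uint8), dtype_max=255, channel_label=img.channel_label
    )


def median_filter(img: ChannelImage, radius: int = 1) -> ChannelImage:
    """Median over the disk neighborhood of ``radius``; borders edge-replicated."""
    if radius < 1:
        raise ValueError("median radius must be >= 1")
    fp = morphology.disk(radius)
    out = ndi.median_filter(img.pixels, footprint=fp, mode="nearest")
    return ChannelImage(pixels=out, dtype_max=img.dtype_max, channel_label=img.channel_label)


def threshold_window(img: ChannelImage, lo: float, hi: float) -> np.ndarray:
    """Boolean mask, true exactly where ``lo <= pixel <= hi`` (inclusive window)."""
    if lo > hi:
        raise ValueError(f"threshold window lo ({lo}) exceeds hi ({hi})")
    p = img.pixels
    return (p >= lo) & (p <= hi)


def morphological_clean(mask: np.ndarray, radius: int = 25) -> np.ndarray:
    """Binary closing then opening with a disk of ``radius``.

    Closing consolidates speckled stain into one blob (fills gaps smaller than
    the element); the subsequent opening removes debris and protrusions smaller
    than the element.
    """
    if radius < 1:
        raise ValueError("morphological radius must be >= 1")
    fp = _disk_footprint(radius, decompose=True)
    mask = np.asarray(mask, dtype=bool)
    closed = morphology.closing(mask, footprint=fp)
    return morphology.opening(closed, footprint=fp)


def label_components(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling (background 0); no watershed splitting."""
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels


def watershed_split(mask: np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Partition foreground into particles by distance-transform watershed.

    Seeds are local maxima of the Euclidean distance transform separated by at
    least ``min_distance`` px; any connected component that receives no seed
    (possible for very small or thin components) is seeded at its deepest
    pixel, so every foreground pixel receives exactly one label >= 1.
    Seed labels are assigned in (row, col) order for determinism.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    comp = label_components(mask)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=comp, exclude_border=False
    )
    seeded = set(comp[r, c] for r, c in peaks)
    extra = []
    for lab in range(1, comp.max() + 1):
        if lab not in seeded:
            inside = comp == lab
            d = np.where(inside, dist, -1.0)
            extra.append(np.unravel_index(np.argmax(d), d.shape))
    coords = sorted(map(tuple, peaks)) + sorted(extra)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(sorted(coords), start=1):
        markers[r, c] = i
    # connectivity 2 so labeling reaches diagonal-only-connected pixels,
    # matching the 8-connected component convention
    return watershed(-dist, markers, mask=mask, connectivity=2).astype(np.int32)
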