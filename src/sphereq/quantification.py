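"""Per-neurosphere integration of nucleus records, and the migration-distance
read-out of the fibronectin outgrowth assay.

Marker combinations are written the way the field writes them, as concatenated
signed marker names ("HU+", "SOX10+PHOX2B+", "SOX10+PHOX2B+HU-"): a nucleus
counts toward a combination when it is positive for every "+" marker and
negative for every "-" marker in it.  Migration is quantified as the five
largest Euclidean distances from detected emigrated cells (or neurite tips) to
the spheroid border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .classification import NucleusRecord
from .io_formats import ChannelImage
from .preprocessing import PreprocessParams, watershed_split
from .segmentation import NUCLEUS_GATE, ParticleGate, RegionOfInterest, find_particles
from .segmentation import _nucleus_mask_stage

__all__ = [
    "NeurosphereSummary",
    "MigrationMeasurement",
    "parse_combination",
    "summarize_roi",
    "measure_border_distances",
    "detect_emigrated_points",
]


@dataclass
class NeurosphereSummary:
    """Integrated per-neurosphere counts and proportions per marker combination.

    ``proportion[combo]`` is ``count / n_nuclei``; for an empty neurosphere it
    is ``None`` (undefined-and-flagged rather than 0 or NaN).
    """

    image_id: str
    roi_id: int
    n_nuclei: int
    n_positive: dict[str, int] = field(default_factory=dict)
    proportion: dict[str, float | None] = field(default_factory=dict)


@dataclass
class MigrationMeasurement:
    """The five largest border distances recorded for one spheroid."""

    spheroid_id: int
    distances: list[float]
    metric_label: str = "cell_distance"

    def __post_init__(self) -> None:
        if len(self.distances) != 5:
            raise ValueError(f"exactly 5 distances required, got {len(self.distances)}")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be >= 0")
        if list(self.distances) != sorted(self.distances, reverse=True):
            raise ValueError("distances must be sorted descending")


def parse_combination(combo: str, markers) -> list[tuple[str, bool]]:
    """Split e.g. ``"SOX10+PHOX2B+HU-"`` into [("SOX10", True), ...].

    Marker names are matched greedily against the known marker set (longest
    first), so names containing hyphens ("far-red") parse unambiguously.
    """
    known = sorted(markers, key=len, reverse=True)
    out = []
    rest = combo
    while rest:
        for name in known:
            if rest.startswith(name) and len(rest) > len(name) and rest[len(name)] in "+-":
                out.append((name, rest[len(name)] == "+"))
                rest = rest[len(name) + 1:]
                break
        else:
            raise ValueError(
                f"cannot parse combination {combo!r} against markers {sorted(markers)}"
            )
    return out


def summarize_roi(
    records: list[NucleusRecord], roi_id: int, combinations: list[str],
    image_id: str = "",
) -> NeurosphereSummary:
    """Count nuclei matching each marker combination within one neurosphere."""
    if any(r.roi_id != roi_id for r in records):
        raise ValueError(f"records carry roi_ids other than {roi_id}")
    n = len(records)
    markers = set()
    for r in records:
        markers.update(r.positive)
    counts: dict[str, int] = {}
    props: dict[str, float | None] = {}
    for combo in combinations:
        terms = parse_combination(combo, markers) if n else []
        k = 0
        for r in records:
            ok = True
            for marker, want_pos in terms:
                if marker not in r.positive:
                    raise KeyError(
                        f"nucleus {r.nucleus_id} has no call for marker {marker!r}"
                    )
                if r.positive[marker] != want_pos:
                    ok = False
                    break
            k += ok
        counts[combo] = k
        props[combo] = (k / n) if n > 0 else None
    return NeurosphereSummary(
        image_id=image_id, roi_id=roi_id, n_nuclei=n,
        n_positive=counts, proportion=props,
    )


def _boundary(mask: np.ndarray) -> np.ndarray:
    er = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return mask & ~er


def measure_border_distances(
    spheroid: RegionOfInterest,
    points,
    metric_label: str = "cell_distance",
) -> MigrationMeasurement:
    """Five largest minimum Euclidean distances from points to the spheroid border.

    Each point's distance is the exact minimum over all boundary pixels of the
    spheroid mask; points must lie outside the spheroid and at least five are
    required.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    shape = spheroid.mask.shape
    bnd_mask = _boundary(spheroid.mask)
    interior = spheroid.mask & ~bnd_mask  # boundary points count as external (distance 0)
    outside = []
    for r, c in pts:
        ri, ci = int(round(r)), int(round(c))
        inside = 0 <= ri < shape[0] and 0 <= ci < shape[1] and interior[ri, ci]
        if not inside:
            outside.append((r, c))
    if len(outside) < 5:
        raise ValueError(
            f"need >= 5 points outside the spheroid, got {len(outside)}"
        )
    bnd = np.argwhere(bnd_mask)
    d = cdist(np.asarray(outside, float), bnd.astype(float)).min(axis=1)
    top5 = sorted((float(x) for x in d), reverse=True)[:5]
    return MigrationMeasurement(
        spheroid_id=spheroid.roi_id, distances=top5, metric_label=metric_label
    )


def detect_emigrated_points(
    marker: ChannelImage,
    spheroid: RegionOfInterest,
    params: PreprocessParams | None = None,
    gate: ParticleGate = NUCLEUS_GATE,
) -> list[tuple[int, int]]:
    """Detect marker-positive particles outside the spheroid and return, per
    particle, the pixel farthest from the spheroid border.

    The farthest pixel (not the centroid) sets the measured length, so neurite
    tips terminate the measurement.  Ties break to the smallest (row, col).
    """
    if params is None:
        params = PreprocessParams(
            rolling_radius=30, threshold_lo=0, threshold_hi=13,
            window_selects="background", median_radius=1, watershed_min_distance=5,
        )
    if marker.shape != spheroid.mask.shape:
        raise ValueError("marker channel and spheroid mask shapes differ")
    mask = _nucleus_mask_stage(marker, params)
    mask &= ~spheroid.mask
    labels = watershed_split(mask, params.watershed_min_distance)
    particles = find_particles(labels, gate)
    # distance of every pixel to the spheroid border
    bnd = _boundary(spheroid.mask)
    dist = ndi.distance_transform_edt(~bnd)
    points = []
    for p in particles:
        rr, cc = np.nonzero(p.mask)
        dvals = dist[rr, cc]
        best = np.flatnonzero(dvals == dvals.max())
        order = np.lexsort((cc[best], rr[best]))
        j = best[order[0]]
        points.append((int(rr[j]), int(cc[j])))
    return points
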