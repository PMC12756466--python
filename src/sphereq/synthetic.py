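"""Synthetic confocal-style benchmark images with exact ground truth.

The generator emulates the kind of data the pipeline quantifies: spheroids
bearing surface neurospheres, rendered as large bright aggregates on the
pan-neuronal channel, with DAPI nuclei drawn as hard disks inside each
spheroid and per-nucleus marker co-expression drawn from configurable
fractions or a full joint sign table (e.g. a declining SOX10+/PHOX2B+
fraction across developmental stages).  Intensities are additive: a flat
background, set-valued object disks, and clipped Gaussian read noise.  All
randomness flows from one integer seed, so stacks and their ground truth are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ChannelImage, ImageStack
from .quantification import parse_combination
from .stats import GroupSample

__all__ = [
    "MarkerModel",
    "SynthesisParams",
    "NucleusTruth",
    "SpheroidTruth",
    "SyntheticGroundTruth",
    "GenerationError",
    "generate_stack",
    "MigrationField",
    "generate_migration_field",
    "GroupSpec",
    "generate_group_dataset",
    "PRESETS",
]


class GenerationError(RuntimeError):
    """Raised when the requested geometry cannot be packed."""


@dataclass
class MarkerModel:
    """Intensity model of one marker channel: positive fraction and the
    rendered disk intensities of positive/negative nuclei (8-bit a.u.)."""

    fraction_positive: float
    mu_pos: float = 120.0
    mu_neg: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_positive <= 1:
            raise ValueError("fraction_positive must be in [0, 1]")
        if not self.mu_pos > self.mu_neg >= 0:
            raise ValueError("marker model requires mu_pos > mu_neg >= 0")


def _default_markers() -> dict[str, MarkerModel]:
    # green = PHOX2B, red = SOX10, far-red = EdU
    return {
        "green": MarkerModel(0.7),
        "red": MarkerModel(0.5),
        "far-red": MarkerModel(0.3),
    }


@dataclass
class SynthesisParams:
    """Study conditions of one synthetic acquisition.

    ``min_separation`` is the minimum edge-to-edge gap between nuclei in px
    (centroid distance >= r_i + r_j + min_separation), so planted counts are
    recoverable by watershed at any positive gap.  Defaults describe a
    two-spheroid field whose spheroids pass the 1,000-50,000 px² neurosphere
    gate and whose nuclei pass the 10-1,000 px² nucleus gate.
    """

    image_shape: tuple[int, int] = (512, 768)
    n_spheroids: int = 2
    spheroid_radius_range: tuple[float, float] = (105.0, 120.0)
    n_nuclei_per_spheroid: int | tuple[int, int] = (50, 200)
    nucleus_radius_range: tuple[float, float] = (3.0, 4.5)
    min_separation: float = 2.0
    nucleus_intensity: float = 200.0
    spheroid_intensity: float = 80.0
    marker_model: dict[str, MarkerModel] = field(default_factory=_default_markers)
    co_expression: dict[str, float] | None = None
    background_level: float = 4.0
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.co_expression is not None:
            total = sum(self.co_expression.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"co_expression probabilities sum to {total}, not 1")


@dataclass
class NucleusTruth:
    spheroid_id: int
    centroid: tuple[float, float]
    radius: float
    signs: dict[str, bool]


@dataclass
class SpheroidTruth:
    spheroid_id: int
    centroid: tuple[float, float]
    radius: float


@dataclass
class SyntheticGroundTruth:
    nuclei: list[NucleusTruth]
    spheroids: list[SpheroidTruth]
    params: SynthesisParams

    def marker_fraction(self, combo: str) -> float:
        """Realized fraction of nuclei matching a signed marker combination."""
        if not self.nuclei:
            return float("nan")
        terms = parse_combination(combo, self.nuclei[0].signs.keys())
        hits = sum(
            all(n.signs[m] == want for m, want in terms) for n in self.nuclei
        )
        return hits / len(self.nuclei)


def _paint_disk(canvas: np.ndarray, center, radius: float, value: float) -> None:
    r, c = center
    r0 = max(0, int(np.floor(r - radius)))
    r1 = min(canvas.shape[0], int(np.ceil(r + radius)) + 1)
    c0 = max(0, int(np.floor(c - radius)))
    c1 = min(canvas.shape[1], int(np.ceil(c + radius)) + 1)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    inside = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    canvas[r0:r1, c0:c1][inside] = value


def disk_mask(shape, center, radius: float) -> np.ndarray:
    m = np.zeros(shape, dtype=float)
    _paint_disk(m, center, radius, 1.0)
    return m.astype(bool)


def _place_spheroids(rng, params) -> list[SpheroidTruth]:
    rows, cols = params.image_shape
    placed: list[SpheroidTruth] = []
    for sid in range(1, params.n_spheroids + 1):
        for _ in range(500):
            rad = rng.uniform(*params.spheroid_radius_range)
            margin = rad + 5
            if rows - margin <= margin or cols - margin <= margin:
                raise GenerationError(
                    f"spheroid radius {rad:.0f} cannot fit in image {params.image_shape}"
                )
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if all(
                np.hypot(r - s.centroid[0], c - s.centroid[1]) >= rad + s.radius + 10
                for s in placed
            ):
                placed.append(SpheroidTruth(sid, (r, c), rad))
                break
        else:
            raise GenerationError(
                f"could not place spheroid {sid} after 500 attempts"
            )
    return placed


def _place_nuclei(rng, spheroid: SpheroidTruth, n: int, params) -> list[tuple[float, float, float]]:
    """Rejection-sample n hard disks inside the spheroid at the required gap."""
    centers_r = np.empty(n)
    centers_c = np.empty(n)
    radii = np.empty(n)
    k = 0
    max_attempts = 50000 + 2000 * n
    attempts = 0
    while k < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"packed only {k}/{n} nuclei into spheroid of radius "
                f"{spheroid.radius:.0f} after {max_attempts} attempts"
            )
        rad = rng.uniform(*params.nucleus_radius_range)
        max_r = spheroid.radius - rad - 1.0
        if max_r <= 0:
            raise GenerationError("nucleus larger than spheroid")
        rho = max_r * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        r = spheroid.centroid[0] + rho * np.cos(theta)
        c = spheroid.centroid[1] + rho * np.sin(theta)
        if k:
            d = np.hypot(centers_r[:k] - r, centers_c[:k] - c)
            if (d < radii[:k] + rad + params.min_separation).any():
                continue
        centers_r[k] = r
        centers_c[k] = c
        radii[k] = rad
        k += 1
    return list(zip(centers_r, centers_c, radii))


def _draw_signs(rng, n: int, params) -> list[dict[str, bool]]:
    markers = list(params.marker_model)
    if params.co_expression is None:
        draws = {m: rng.random(n) < params.marker_model[m].fraction_positive
                 for m in markers}
        return [{m: bool(draws[m][i]) for m in markers} for i in range(n)]
    combos = list(params.co_expression)
    probs = np.array([params.co_expression[c] for c in combos], dtype=float)
    probs = probs / probs.sum()
    sign_maps = []
    for c in combos:
        terms = dict(parse_combination(c, markers))
        if set(terms) != set(markers):
            raise ValueError(
                f"co_expression combination {c!r} must sign every marker {markers}"
            )
        sign_maps.append(terms)
    picks = rng.choice(len(combos), size=n, p=probs)
    return [dict(sign_maps[k]) for k in picks]


def generate_stack(params: SynthesisParams) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a multichannel stack (DAPI, HU, one plane per marker) plus truth.

    The DAPI channel draws every nucleus as a disk of ``nucleus_intensity``;
    the HU channel draws each spheroid body at ``spheroid_intensity`` (with
    per-nucleus HU disks on top when "HU" is among the markers); each marker
    channel draws ``mu_pos`` or ``mu_neg`` per the nucleus's planted sign.
    Identical seeds give identical stacks and truth.
    """
    rng = np.random.default_rng(params.seed)
    spheroids = _place_spheroids(rng, params)
    nuclei: list[NucleusTruth] = []
    for sph in spheroids:
        n = params.n_nuclei_per_spheroid
        if not isinstance(n, int):
            n = int(rng.integers(n[0], n[1] + 1))
        disks = _place_nuclei(rng, sph, n, params)
        signs = _draw_signs(rng, n, params)
        for (r, c, rad), sg in zip(disks, signs):
            nuclei.append(NucleusTruth(sph.spheroid_id, (r, c), rad, sg))

    markers = list(params.marker_model)
    labels = ["DAPI", "HU"] + [m for m in markers if m != "HU"]
    canvases = {
        lab: np.full(params.image_shape, params.background_level, dtype=np.float64)
        for lab in labels
    }
    for sph in spheroids:
        _paint_disk(canvases["HU"], sph.centroid, sph.radius, params.spheroid_intensity)
    for nuc in nuclei:
        _paint_disk(canvases["DAPI"], nuc.centroid, nuc.radius, params.nucleus_intensity)
        for m in markers:
            model = params.marker_model[m]
            value = model.mu_pos if nuc.signs[m] else model.mu_neg
            _paint_disk(canvases[m], nuc.centroid, nuc.radius, value)

    channels = []
    for lab in labels:
        img = canvases[lab]
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        channels.append(ChannelImage(pixels=img, dtype_max=255, channel_label=lab))
    return ImageStack(channels=channels), SyntheticGroundTruth(nuclei, spheroids, params)


# ---------------------------------------------------------------------------
# Migration fields
# ---------------------------------------------------------------------------


@dataclass
class MigrationField:
    """A rendered outgrowth assay: central spheroid plus emigrated cells.

    ``planted_distances`` are the exact border distances of the rendered cell
    disks (max over cell pixels of the min distance to the rasterized spheroid
    boundary), sorted descending.  Unpacks as ``stack, distances = field``.
    """

    stack: ImageStack
    planted_distances: list[float]
    spheroid_center: tuple[float, float]
    spheroid_radius: float
    cell_centers: list[tuple[float, float]]
    cell_radius: float

    def spheroid_mask(self) -> np.ndarray:
        return disk_mask(self.stack.shape, self.spheroid_center, self.spheroid_radius)

    def __iter__(self):
        return iter((self.stack, self.planted_distances))


def generate_migration_field(
    spheroid_radius: float,
    cell_offsets,
    seed: int = 0,
    cell_radius: float = 3.0,
    cell_intensity: float = 180.0,
    spheroid_intensity: float = 180.0,
    background_level: float = 4.0,
    noise_sigma: float = 4.0,
    channel_label: str = "TUJ1",
) -> MigrationField:
    """Render a central spheroid with marker-positive cells at the given radial
    offsets (border to cell center, px) at deterministic jittered angles."""
    offsets = [float(o) for o in cell_offsets]
    if any(o < 0 for o in offsets):
        raise ValueError("cell offsets must be >= 0")
    rng = np.random.default_rng(seed)
    pad = 15.0
    half = spheroid_radius + (max(offsets) if offsets else 0) + cell_radius + pad
    side = int(np.ceil(2 * half))
    center = (side / 2.0, side / 2.0)
    canvas = np.full((side, side), background_level, dtype=np.float64)
    _paint_disk(canvas, center, spheroid_radius, spheroid_intensity)
    n = len(offsets)
    rot = rng.uniform(0, 2 * np.pi)
    cell_centers = []
    for i, off in enumerate(offsets):
        ang = rot + 2 * np.pi * (i + 0.25 * rng.uniform(-1, 1)) / max(n, 1)
        rho = spheroid_radius + off
        r = center[0] + rho * np.cos(ang)
        c = center[1] + rho * np.sin(ang)
        cell_centers.append((r, c))
        _paint_disk(canvas, (r, c), cell_radius, cell_intensity)
    if noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise_sigma, size=canvas.shape)
    img = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    stack = ImageStack(
        channels=[ChannelImage(pixels=img, dtype_max=255, channel_label=channel_label)]
    )
    # exact planted distances on the rasterized geometry
    from scipy import ndimage as ndi

    smask = disk_mask((side, side), center, spheroid_radius)
    er = ndi.binary_erosion(smask, structure=np.ones((3, 3), bool), border_value=0)
    bnd = np.argwhere(smask & ~er).astype(float)
    planted = []
    for (r, c) in cell_centers:
        cmask = disk_mask((side, side), (r, c), cell_radius) & ~smask
        px = np.argwhere(cmask).astype(float)
        if px.size == 0:
            continue
        d = np.sqrt(((px[:, None, :] - bnd[None, :, :]) ** 2).sum(-1)).min(axis=1)
        planted.append(float(d.max()))
    planted.sort(reverse=True)
    return MigrationField(
        stack=stack,
        planted_distances=planted,
        spheroid_center=center,
        spheroid_radius=spheroid_radius,
        cell_centers=cell_centers,
        cell_radius=cell_radius,
    )


# ---------------------------------------------------------------------------
# Group datasets for the statistics layer
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    n: int
    dist: str = "normal"  # "normal" | "lognormal"
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.dist not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.dist!r}")


def generate_group_dataset(group_specs: dict[str, GroupSpec], seed: int = 0) -> list[GroupSample]:
    """Draw one sample per group from its stated distribution, deterministically."""
    rng = np.random.default_rng(seed)
    out = []
    for label, spec in group_specs.items():
        if spec.dist == "normal":
            vals = rng.normal(spec.loc, spec.scale, size=spec.n)
        else:
            vals = rng.lognormal(spec.loc, spec.scale, size=spec.n)
        out.append(GroupSample(group_label=label, values=vals))
    return out


# Illustrative developmental-stage presets: the green (PHOX2B) x red (SOX10)
# joint fraction declines from the youngest stage to hatching, with a matching
# drop in far-red (EdU) labeling.  Values are defaults for demonstration, not
# measurements.
def _preset(joint_gr: dict[str, float], edu: float) -> dict[str, float]:
    table = {}
    for combo, p in joint_gr.items():
        table[combo + "far-red+"] = p * edu
        table[combo + "far-red-"] = p * (1 - edu)
    return table


PRESETS: dict[str, dict[str, float]] = {
    "e8": _preset({"green+red+": 0.60, "green+red-": 0.15,
                   "green-red+": 0.15, "green-red-": 0.10}, edu=0.35),
    "e12": _preset({"green+red+": 0.30, "green+red-": 0.35,
                    "green-red+": 0.20, "green-red-": 0.15}, edu=0.25),
    "d0": _preset({"green+red+": 0.05, "green+red-": 0.55,
                   "green-red+": 0.25, "green-red-": 0.15}, edu=0.10),
}
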