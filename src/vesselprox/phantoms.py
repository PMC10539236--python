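"""Synthetic vascular phantoms with known ground truth.

Real contrast-perfused organ scans are large and not generally shareable, so
every stage of the pipeline is exercised instead on parametric 3D vascular
geometries rasterized to grayscale volumes:

``krogh_array``
    Parallel capillaries on a square lattice (axes along z), the classical
    Krogh supply geometry extended to a lattice.  The fraction of tissue
    within distance d of a vessel has an exact closed form
    (:func:`analytic_krogh_fraction`), making this the quantitative oracle.
``random_cylinders``
    Uniformly random chords through the domain — an isotropic disordered
    network with natural sample-to-sample variability.
``branching_tree``
    Recursive dichotomous branching with configurable length/radius ratios
    and angle jitter; no physiological (Murray's-law) calibration is claimed.

A stochastic rarefaction operator removes a fraction of network elements
(lattice lines, cylinders, or terminal branches) to emulate capillary
rarefaction, the loss of microvessels seen in chronic kidney disease.

All randomness flows from the spec's integer seed through
``numpy.random.default_rng``; identical spec -> bit-identical volume.
Voxels are vessel iff their *center* lies within ``vessel_radius_um`` of a
geometry axis, matching the voxel-center metric of the distance transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .volume import BinaryVolume, VolumeImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Capsule",
    "generate_phantom",
    "analytic_krogh_fraction",
    "analytic_enclosed_krogh_fraction",
    "rarefy_network",
]

GEOMETRIES = ("krogh_array", "random_cylinders", "branching_tree")


@dataclass(frozen=True)
class Capsule:
    """A finite cylinder with hemispherical caps: all points within
    ``radius_um`` of the segment ``p0 -> p1`` (physical (z, y, x) um)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_um: float
    level: int = 0  # branching depth; 0 for non-tree geometries


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic vascular phantom.

    ``domain_shape_um`` is (z, y, x) physical extent.  Geometry-specific
    fields: ``spacing_um`` (krogh_array lattice pitch), ``n_cylinders`` and
    ``orientation`` (random_cylinders), ``branch_levels`` / ``length_ratio``
    / ``radius_ratio`` / ``angle_jitter_deg`` (branching_tree).
    ``removed_elements`` holds indices dropped by rarefaction.

    ``enclosed`` adds a vessel shell of thickness ``wall_um`` on every domain
    face — a feed manifold standing in for the supplying vasculature.  A bare
    parallel lattice is a set of mutually disconnected tubes, which no real
    perfused network is; the shell joins every element into one connected
    component so the largest-component cleanup is lossless, and (for
    krogh_array) keeps the closed-form ground truth exact
    (:func:`analytic_enclosed_krogh_fraction`).  The shell never counts as a
    removable element for rarefaction.
    """

    geometry: str
    domain_shape_um: tuple[float, float, float] = (200.0, 200.0, 200.0)
    voxel_size_um: float = 2.0
    vessel_radius_um: float = 10.0
    spacing_um: float = 100.0
    n_cylinders: int = 40
    orientation: str = "uniform"
    branch_levels: int = 5
    length_ratio: float = 0.75
    radius_ratio: float = 0.8
    angle_jitter_deg: float = 15.0
    enclosed: bool = False
    wall_um: float = 4.0
    foreground: float = 200.0
    background: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0
    removed_elements: tuple[int, ...] = ()

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ParameterError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )
        dom = tuple(float(d) for d in self.domain_shape_um)
        if len(dom) != 3 or any(d <= 0 for d in dom):
            raise ParameterError(f"domain_shape_um must be 3 positive scalars, got {dom}")
        if self.voxel_size_um <= 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.vessel_radius_um < self.voxel_size_um:
            raise ParameterError(
                f"vessel_radius_um ({self.vessel_radius_um}) must be >= "
                f"voxel_size_um ({self.voxel_size_um}) or the vessel under-resolves"
            )
        if min(dom) < 4 * self.vessel_radius_um:
            raise ParameterError(
                f"domain dims {dom} must be >= 4 x vessel_radius_um "
                f"({4 * self.vessel_radius_um})"
            )
        if self.geometry == "krogh_array" and self.spacing_um < 2 * self.vessel_radius_um:
            raise ParameterError(
                f"infeasible lattice: spacing_um ({self.spacing_um}) < "
                f"2 x vessel_radius_um ({2 * self.vessel_radius_um})"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.enclosed and not (0 < self.wall_um < min(dom) / 2):
            raise ParameterError(
                f"wall_um must be in (0, {min(dom) / 2}), got {self.wall_um}"
            )
        object.__setattr__(self, "domain_shape_um", dom)
        object.__setattr__(self, "removed_elements",
                           tuple(sorted(int(i) for i in self.removed_elements)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            max(1, int(round(d / self.voxel_size_um))) for d in self.domain_shape_um
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    vessel: BinaryVolume
    vessel_volume_fraction: float
    analytic_fraction_within: dict | None  # only for intact krogh_array
    elements: tuple[Capsule, ...]


# ---------------------------------------------------------------------------
# geometry construction


def _element_rng(spec: PhantomSpec) -> np.random.Generator:
    # separate stream from the noise so rarefaction never shifts the noise
    return np.random.default_rng([int(spec.seed), 0xE1E])


def _krogh_elements(spec: PhantomSpec) -> list[Capsule]:
    # origin-aligned lattice: lines at every multiple of the spacing that
    # falls inside the domain, so the periodic nearest-axis field of the
    # infinite lattice is realised everywhere in the box (closed forms exact)
    Z, Y, X = spec.domain_shape_um
    s = spec.spacing_um
    ny = int(math.floor(Y / s + 1e-9))
    nx = int(math.floor(X / s + 1e-9))
    out = []
    for j in range(ny + 1):
        for i in range(nx + 1):
            y = j * s
            x = i * s
            out.append(Capsule((0.0, y, x), (Z, y, x), spec.vessel_radius_um))
    return out


def _random_cylinder_elements(spec: PhantomSpec) -> list[Capsule]:
    rng = _element_rng(spec)
    Z, Y, X = spec.domain_shape_um
    lo = np.zeros(3)
    hi = np.array([Z, Y, X])
    out = []
    for _ in range(spec.n_cylinders):
        c = rng.uniform(lo, hi)
        if spec.orientation == "axial":
            d = np.array([1.0, 0.0, 0.0])
        else:  # uniform on the sphere
            v = rng.normal(size=3)
            d = v / np.linalg.norm(v)
        # clip the line c + t*d to the domain box (slab method)
        t0, t1 = -np.inf, np.inf
        for k in range(3):
            if abs(d[k]) < 1e-12:
                continue
            a = (lo[k] - c[k]) / d[k]
            b = (hi[k] - c[k]) / d[k]
            t0 = max(t0, min(a, b))
            t1 = min(t1, max(a, b))
        p0 = c + t0 * d
        p1 = c + t1 * d
        out.append(Capsule(tuple(p0), tuple(p1), spec.vessel_radius_um))
    return out


def _rotate_about(u: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle theta from u, azimuth phi in u's normal plane."""
    # any vector not parallel to u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return math.cos(theta) * u + math.sin(theta) * (
        math.cos(phi) * e1 + math.sin(phi) * e2
    )


def _tree_elements(spec: PhantomSpec) -> list[Capsule]:
    rng = _element_rng(spec)
    Z, Y, X = spec.domain_shape_um
    root_len = 0.35 * Z
    branch_angle = math.radians(30.0)
    jitter = math.radians(spec.angle_jitter_deg)
    out: list[Capsule] = []
    # (start point, unit direction, length, radius, level)
    frontier = [(np.array([0.0, Y / 2, X / 2]), np.array([1.0, 0.0, 0.0]),
                 root_len, spec.vessel_radius_um, 0)]
    for level in range(spec.branch_levels + 1):
        next_frontier = []
        for p0, u, length, radius, lev in frontier:
            p1 = p0 + length * u
            out.append(Capsule(tuple(p0), tuple(p1), radius, level=lev))
            if lev < spec.branch_levels:
                phi = rng.uniform(0.0, 2 * math.pi)
                for dphi in (0.0, math.pi):
                    theta = branch_angle + rng.uniform(-jitter, jitter)
                    v = _rotate_about(u, theta, phi + dphi)
                    next_frontier.append(
                        (p1, v, length * spec.length_ratio,
                         max(radius * spec.radius_ratio, spec.voxel_size_um), lev + 1)
                    )
        frontier = next_frontier
    return out


def build_elements(spec: PhantomSpec, *, include_removed: bool = False) -> list[Capsule]:
    """Deterministic capsule list for a spec; removed elements dropped unless
    ``include_removed``."""
    builder = {
        "krogh_array": _krogh_elements,
        "random_cylinders": _random_cylinder_elements,
        "branching_tree": _tree_elements,
    }[spec.geometry]
    elements = builder(spec)
    if include_removed:
        return elements
    removed = set(spec.removed_elements)
    return [e for i, e in enumerate(elements) if i not in removed]


# ---------------------------------------------------------------------------
# rasterization


def _rasterize(spec: PhantomSpec, elements: Sequence[Capsule]) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_um
    mask = np.zeros((nz, ny, nx), dtype=bool)
    centers = [
        (np.arange(n) + 0.5) * v for n in (nz, ny, nx)
    ]
    for cap in elements:
        p0 = np.asarray(cap.p0)
        p1 = np.asarray(cap.p1)
        R = cap.radius_um
        lo_um = np.minimum(p0, p1) - R
        hi_um = np.maximum(p0, p1) + R
        lo = np.maximum(np.floor(lo_um / v - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / v + 0.5).astype(int) + 1, [nz, ny, nx])
        if np.any(lo >= hi):
            continue
        zc = centers[0][lo[0]:hi[0]][:, None, None]
        yc = centers[1][lo[1]:hi[1]][None, :, None]
        xc = centers[2][lo[2]:hi[2]][None, None, :]
        w = p1 - p0
        L2 = float(w @ w)
        if L2 == 0:
            d2 = (zc - p0[0]) ** 2 + (yc - p0[1]) ** 2 + (xc - p0[2]) ** 2
        else:
            t = ((zc - p0[0]) * w[0] + (yc - p0[1]) * w[1] + (xc - p0[2]) * w[2]) / L2
            np.clip(t, 0.0, 1.0, out=t)
            d2 = (
                (p0[0] + t * w[0] - zc) ** 2
                + (p0[1] + t * w[1] - yc) ** 2
                + (p0[2] + t * w[2] - xc) ** 2
            )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= R * R
    return mask


def _rasterize_walls(spec: PhantomSpec, mask: np.ndarray) -> None:
    """Mark every voxel whose center lies within ``wall_um`` of a domain face."""
    v = spec.voxel_size_um
    for axis, n in enumerate(mask.shape):
        centers = (np.arange(n) + 0.5) * v
        near = (centers < spec.wall_um) | (centers > spec.domain_shape_um[axis] - spec.wall_um)
        idx = [slice(None)] * 3
        idx[axis] = near
        mask[tuple(idx)] = True


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Rasterize a phantom spec to a grayscale volume plus ground truth.

    The grayscale volume is ``background`` off-vessel and ``foreground``
    on-vessel, with optional additive Gaussian noise of sd ``noise_sd``
    (seeded; same spec -> bit-identical output).
    """
    elements = build_elements(spec)
    mask = _rasterize(spec, elements)
    if spec.enclosed:
        _rasterize_walls(spec, mask)
    gray = np.where(mask, np.float32(spec.foreground), np.float32(spec.background))
    if spec.noise_sd > 0:
        rng = np.random.default_rng([int(spec.seed), 0x0153])
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape).astype(np.float32)
    name = f"{spec.geometry}_seed{spec.seed}"
    if spec.removed_elements:
        name += f"_rarefied{len(spec.removed_elements)}"
    volume = VolumeImage(gray, spec.voxel_size_um, name=name)
    analytic = None
    if spec.geometry == "krogh_array" and not spec.removed_elements:
        analytic = {}
        for d in (20.0, 100.0):
            if spec.enclosed:
                try:
                    analytic[d] = analytic_enclosed_krogh_fraction(spec, d)
                except ParameterError:
                    continue  # window not phase-complete: no exact truth at this d
            else:
                analytic[d] = analytic_krogh_fraction(
                    spec.spacing_um, spec.vessel_radius_um, d
                )
        analytic = analytic or None
    truth = PhantomTruth(
        vessel=BinaryVolume(mask, spec.voxel_size_um, kind="vessel", name=name),
        vessel_volume_fraction=float(mask.mean()),
        analytic_fraction_within=analytic,
        elements=tuple(elements),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# analytic ground truth and rarefaction


def analytic_krogh_fraction(
    spacing_um: float, vessel_radius_um: float, d_um: float
) -> float:
    """Exact tissue fraction within distance d of the nearest vessel surface
    for an infinite square lattice of parallel capillaries.

    By periodicity this is the area fraction of the square unit cell
    (half-width h = spacing/2, capillary axis at the center) covered by a
    disc of radius R = vessel_radius + d: pi R^2 / spacing^2 while the disc
    fits inside the cell (R <= h), 1.0 once it covers the cell corners
    (R >= h * sqrt(2)), and the exact disc-square intersection in between.
    Vessel lumen (distance <= 0) counts as covered.
    """
    if spacing_um <= 2 * vessel_radius_um:
        raise ParameterError(
            f"spacing_um ({spacing_um}) must exceed 2 x vessel_radius_um"
        )
    if d_um <= 0:
        raise ParameterError(f"d_um must be positive, got {d_um}")
    R = vessel_radius_um + d_um
    h = spacing_um / 2.0
    if R >= h * math.sqrt(2.0):
        return 1.0
    if R <= h:
        return math.pi * R * R / (spacing_um * spacing_um)
    # disc crosses the cell sides: quadrant area = a*h + integral of the arc
    a = math.sqrt(R * R - h * h)

    def arc_integral(x):  # antiderivative of sqrt(R^2 - x^2)
        return 0.5 * (x * math.sqrt(R * R - x * x) + R * R * math.asin(x / R))

    quadrant = a * h + (arc_integral(h) - arc_integral(a))
    return 4.0 * quadrant / (spacing_um * spacing_um)


def analytic_enclosed_krogh_fraction(spec: PhantomSpec, d_um: float) -> float:
    """Exact tissue fraction within d for an *enclosed* Krogh lattice phantom.

    Decompose the domain box: every point within ``wall_um + d`` of a face is
    within d of the shell, hence covered; the interior window is covered iff
    within d of the lattice.  When the lateral window lengths are integer
    multiples of the lattice spacing the window is phase-complete and the
    interior fraction is exactly :func:`analytic_krogh_fraction`, so

        f(d) = 1 - (V_interior / V) * (1 - f_krogh(d)).

    Raises :class:`ParameterError` when the window is not phase-complete
    (no closed form then).
    """
    if spec.geometry != "krogh_array" or not spec.enclosed:
        raise ParameterError("exact enclosed fraction needs an enclosed krogh_array spec")
    fk = analytic_krogh_fraction(spec.spacing_um, spec.vessel_radius_um, d_um)
    Z, Y, X = spec.domain_shape_um
    m = spec.wall_um + d_um
    wz, wy, wx = Z - 2 * m, Y - 2 * m, X - 2 * m
    if min(wz, wy, wx) <= 0:
        return 1.0  # shell halo alone covers the whole box
    if fk < 1.0:
        s = spec.spacing_um
        for L, w in (((Y, wy)), ((X, wx))):
            if abs(w / s - round(w / s)) > 1e-9:
                raise ParameterError(
                    f"interior window {w} um is not a multiple of the lattice "
                    f"spacing {s} um; no phase-complete closed form"
                )
            # outermost actual line must serve the window's far edge
            overhang = L - math.floor(L / s + 1e-9) * s
            if overhang > s / 2 + m + 1e-9:
                raise ParameterError(
                    "domain overhangs the outermost lattice line by more than "
                    "spacing/2 + wall + d; periodic field not realised"
                )
    v_frac = (wz * wy * wx) / (Z * Y * X)
    return 1.0 - v_frac * (1.0 - fk)


def rarefy_network(
    spec: PhantomSpec, removal_fraction: float, seed: int
) -> PhantomSpec:
    """Remove a random fraction of network elements (seeded), returning a new spec.

    ``floor(removal_fraction * n)`` elements are removed uniformly at random
    among the removable ones — every lattice line or cylinder, but only
    *terminal* branches of a tree.  ``removal_fraction = 0`` returns the spec
    unchanged.  Composing rarefactions removes from the remaining elements.
    """
    if not (0.0 <= removal_fraction <= 1.0):
        raise ParameterError(
            f"removal_fraction must be in [0, 1], got {removal_fraction}"
        )
    all_elements = build_elements(spec, include_removed=True)
    already = set(spec.removed_elements)
    if spec.geometry == "branching_tree":
        max_level = max((e.level for e in all_elements), default=0)
        removable = [i for i, e in enumerate(all_elements)
                     if e.level == max_level and i not in already]
    else:
        removable = [i for i in range(len(all_elements)) if i not in already]
    k = int(math.floor(removal_fraction * len(removable)))
    if k == 0:
        return spec
    rng = np.random.default_rng([int(seed), 0xDEAD])
    chosen = rng.choice(len(removable), size=k, replace=False)
    removed = already | {removable[int(i)] for i in chosen}
    return replace(spec, removed_elements=tuple(sorted(removed)))
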