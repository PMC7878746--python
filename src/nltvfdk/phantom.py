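"""Analytic ellipsoid phantoms and the synthetic cone-beam acquisition model.

The simulator stands in for a physical Catphan-style scan: it computes
closed-form line integrals through a set of (possibly overlapping,
additive) ellipsoids, converts them to photon counts with Beer-Lambert,
adds Poisson counting noise for the low-mAs protocol, and log-transforms
back to line integrals.  Ellipsoids may be rotated about z and carry an
attenuation increment ``dmu`` in mm^-1 (negative for low-density inserts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ConeBeamGeometry
from .projections import ProjectionStack

__all__ = [
    "Ellipsoid",
    "EllipsoidPhantom",
    "line_integral",
    "forward_project",
    "to_intensity",
    "add_poisson_noise",
    "log_transform",
    "catphan_like",
    "CATPHAN_INSERTS",
    "insert_center",
    "voxelize",
]


@dataclass(frozen=True)
class Ellipsoid:
    """One ellipsoid: center (mm), semi-axes (mm), z-rotation (rad), dmu (mm^-1)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rot_z: float = 0.0
    dmu: float = 0.0

    def __post_init__(self) -> None:
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if not np.isfinite(self.dmu):
            raise ValueError("dmu must be finite")


@dataclass(frozen=True)
class EllipsoidPhantom:
    """Additive collection of ellipsoids; attenuations sum where they overlap."""

    ellipsoids: tuple[Ellipsoid, ...] = ()

    @classmethod
    def from_records(cls, records) -> "EllipsoidPhantom":
        """Build from a list of dicts (config-file ellipsoid records)."""
        ells = tuple(
            Ellipsoid(
                center=tuple(float(x) for x in r["center_mm"]),
                semi_axes=tuple(float(x) for x in r["semi_axes_mm"]),
                rot_z=float(np.radians(r.get("rot_z_deg", 0.0))),
                dmu=float(r["dmu_per_mm"]),
            )
            for r in records
        )
        return cls(ells)

    def to_records(self) -> list[dict]:
        return [
            {
                "center_mm": list(e.center),
                "semi_axes_mm": list(e.semi_axes),
                "rot_z_deg": float(np.degrees(e.rot_z)),
                "dmu_per_mm": float(e.dmu),
            }
            for e in self.ellipsoids
        ]


def _to_ellipsoid_frame(e: Ellipsoid, pts: np.ndarray) -> np.ndarray:
    """World points -> unit-sphere frame of the ellipsoid (shape (..., 3))."""
    p = pts - np.asarray(e.center)
    c, s = np.cos(e.rot_z), np.sin(e.rot_z)
    x = c * p[..., 0] + s * p[..., 1]
    y = -s * p[..., 0] + c * p[..., 1]
    z = p[..., 2]
    ax = np.asarray(e.semi_axes)
    return np.stack([x / ax[0], y / ax[1], z / ax[2]], axis=-1)


def line_integral(phantom: EllipsoidPhantom, src, dst):
    """Path attenuation of the straight segment(s) src -> dst.

    ``src``/``dst`` are broadcastable arrays of shape ``(..., 3)`` in mm.
    For each ellipsoid the segment is mapped to the unit-sphere frame and
    the two quadratic roots give the chord, clipped to the [0, 1] segment
    parameter; the result is ``sum(dmu * chord_length)`` (dimensionless).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    src, dst = np.broadcast_arrays(src, dst)
    seg = dst - src
    seg_len = np.linalg.norm(seg, axis=-1)
    if np.any(seg_len == 0):
        raise ValueError("src and dst must differ")
    total = np.zeros(src.shape[:-1], dtype=float)
    for e in phantom.ellipsoids:
        p0 = _to_ellipsoid_frame(e, src)
        p1 = _to_ellipsoid_frame(e, dst)
        d = p1 - p0
        # |p0 + t d|^2 = 1
        a = np.sum(d * d, axis=-1)
        b = 2.0 * np.sum(p0 * d, axis=-1)
        c = np.sum(p0 * p0, axis=-1) - 1.0
        disc = b * b - 4.0 * a * c
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2.0 * a)
            t2 = (-b + sq) / (2.0 * a)
        t1 = np.clip(t1, 0.0, 1.0)
        t2 = np.clip(t2, 0.0, 1.0)
        frac = np.where(hit, t2 - t1, 0.0)
        total += e.dmu * frac * seg_len
    return total


def forward_project(
    phantom: EllipsoidPhantom,
    geom: ConeBeamGeometry,
    oversample: int = 1,
) -> ProjectionStack:
    """Ideal (noise-free) log-domain projections, one ray per pixel center.

    ``oversample`` > 1 averages an ``oversample x oversample`` sub-pixel ray
    grid per detector pixel.
    """
    n, nv, nu = geom.n_projections, geom.n_v, geom.n_u
    out = np.zeros((n, nv, nu), dtype=float)
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    offs = (np.arange(oversample) + 0.5) / oversample - 0.5
    for i, theta in enumerate(geom.angles):
        src = geom.source_position(theta)
        acc = np.zeros((nv, nu), dtype=float)
        for ou in offs:
            for ov in offs:
                uu, vv = np.meshgrid(
                    np.arange(nu, dtype=float) + ou,
                    np.arange(nv, dtype=float) + ov,
                )
                dst = geom.detector_pixel_position(theta, uu, vv)
                acc += line_integral(phantom, src, dst)
        out[i] = acc / (oversample * oversample)
    return ProjectionStack(out, geom, domain="log")


def to_intensity(stack: ProjectionStack, i0: float) -> ProjectionStack:
    """Beer-Lambert: I = I0 * exp(-P).  ``i0`` is the unattenuated count."""
    stack.require_domain("log")
    if not (i0 > 0):
        raise ValueError("i0 must be positive")
    return stack.with_values(i0 * np.exp(-stack.values), domain="intensity")


def add_poisson_noise(stack: ProjectionStack, seed: int) -> ProjectionStack:
    """Replace each pixel by a Poisson draw with that mean (low-mAs noise).

    Zero counts are clamped to 1 so the subsequent log transform stays
    finite.  Reproducible for a fixed ``seed``.
    """
    stack.require_domain("intensity")
    if np.any(stack.values <= 0):
        raise ValueError("intensity stack must be strictly positive")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(stack.values).astype(float)
    noisy = np.maximum(noisy, 1.0)
    return stack.with_values(noisy, domain="intensity")


def log_transform(stack: ProjectionStack, i0: float) -> ProjectionStack:
    """Recover line integrals P = ln(I0 / max(I, 1)) from counts."""
    stack.require_domain("intensity")
    if not (i0 > 0):
        raise ValueError("i0 must be positive")
    return stack.with_values(np.log(i0 / np.maximum(stack.values, 1.0)), domain="log")


#: (label, dmu relative to water in mm^-1) of the catphan-like sensitometry
#: rods, in ring order starting at +x and proceeding counter-clockwise.
CATPHAN_INSERTS = [
    ("delrin", +0.007),
    ("teflon", +0.018),
    ("air", -0.02),
    ("pmp", -0.004),
    ("ldpe", -0.002),
    ("polystyrene", -0.001),
    ("air2", -0.02),
]


def catphan_like(
    *,
    mu_water: float = 0.02,
    body_radius: float = 45.0,
    ring_radius: float = 30.0,
    rod_radius: float = 6.25,
    aspect: float = 12.0,
) -> EllipsoidPhantom:
    """Sensitometry-module phantom: water cylinder with seven contrast rods.

    A water-equivalent cylinder (mu = 0.02 mm^-1) carries seven 12.5 mm
    diameter rods on a ring, with attenuation increments spanning
    -0.02 .. +0.02 mm^-1 (air to Teflon-like).  Cylinders are modelled as
    ellipsoids whose z semi-axis is ``aspect`` times the body radius: the
    phantom is axially long compared to any cone-beam field of view (like
    a physical quality-assurance phantom spanning the scan length), the
    cross-section within the imaged region is circular to <0.1%, and the
    rods stay strictly inside the body everywhere the cone samples, so
    line integrals are nonnegative.
    """
    half_len = aspect * body_radius
    body = Ellipsoid(
        center=(0.0, 0.0, 0.0),
        semi_axes=(body_radius, body_radius, half_len),
        dmu=mu_water,
    )
    inserts = []
    for idx, (_, dmu) in enumerate(CATPHAN_INSERTS):
        ang = 2.0 * np.pi * idx / len(CATPHAN_INSERTS)
        cx = ring_radius * np.cos(ang)
        cy = ring_radius * np.sin(ang)
        inserts.append(
            Ellipsoid(
                center=(cx, cy, 0.0),
                semi_axes=(rod_radius, rod_radius, 0.9 * half_len),
                dmu=dmu,
            )
        )
    return EllipsoidPhantom((body, *inserts))


def insert_center(index: int, ring_radius: float = 30.0) -> tuple[float, float]:
    """(x, y) center in mm of insert ``index`` of the catphan-like preset."""
    ang = 2.0 * np.pi * index / len(CATPHAN_INSERTS)
    return (ring_radius * np.cos(ang), ring_radius * np.sin(ang))


def voxelize(
    phantom: EllipsoidPhantom,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    supersample: int = 2,
):
    """Ground-truth attenuation volume (mm^-1), grid centered on the isocenter.

    Each voxel value is the mean of ``supersample^3`` sub-voxel samples of
    the analytic phantom (partial-volume-aware voxelization).
    Returns an array of shape ``(nz, ny, nx)``.
    """
    nz, ny, nx = shape
    vz, vy, vx = voxel_size
    out = np.zeros(shape, dtype=float)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    zc = (np.arange(nz) - (nz - 1) / 2.0) * vz
    yc = (np.arange(ny) - (ny - 1) / 2.0) * vy
    xc = (np.arange(nx) - (nx - 1) / 2.0) * vx
    for oz in offs:
        for oy in offs:
            for ox in offs:
                Z, Y, X = np.meshgrid(
                    zc + oz * vz, yc + oy * vy, xc + ox * vx, indexing="ij"
                )
                pts = np.stack([X, Y, Z], axis=-1)
                acc = np.zeros(shape, dtype=float)
                for e in phantom.ellipsoids:
                    q = _to_ellipsoid_frame(e, pts)
                    inside = np.sum(q * q, axis=-1) <= 1.0
                    acc += e.dmu * inside
                out += acc
    return out / supersample**3
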