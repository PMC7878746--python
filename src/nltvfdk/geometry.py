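"""Circular cone-beam scan geometry.

The scanner is described in a right-handed frame with ``z`` along the
rotation axis.  At gantry angle ``theta = 0`` the source sits at
``(0, -sad, 0)`` and the flat detector panel is perpendicular to ``+y`` at
distance ``sdd`` from the source.  Rotating the gantry by ``theta`` is
equivalent to rotating the object coordinates into the gantry frame with
the standard z-rotation matrix; all per-view mapping below works in that
rotated (gantry) frame.

Detector coordinates follow the virtual-detector-at-isocenter convention:
a point with gantry-frame coordinates ``(rx, ry, rz)`` projects to

    u_iso = sad * rx / (sad + ry)   [mm]
    v_iso = sad * rz / (sad + ry)   [mm]

and physical panel pixels are converted to isocenter-plane units by
dividing the pixel pitch by the magnification ``sdd / sad``.  Continuous
pixel coordinates are 0-based pixel-center coordinates; pixel ``(0, 0)``
is a corner and the central ray hits ``(det_center_u, det_center_v)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "ConeBeamGeometry",
    "rotate_to_gantry_frame",
    "project_to_detector",
    "depth_weight",
]


class GeometryError(ValueError):
    """A voxel/ray configuration that the cone-beam mapping cannot handle."""


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Source-detector distances, detector grid and gantry angle list.

    Parameters
    ----------
    sad:
        Source-to-axis distance ``d`` in mm.
    sdd:
        Source-to-detector distance in mm (``sdd >= sad``).
    n_u, n_v:
        Detector pixel counts along the row (``u``) and column (``v``)
        directions.
    pitch_u, pitch_v:
        Physical detector pixel size in mm.
    angles:
        Gantry angles in radians, one per projection.
    det_center_u, det_center_v:
        Detector pixel coordinate of the ray through the isocenter.
        Defaults to the grid center ``(n - 1) / 2``.
    """

    sad: float
    sdd: float
    n_u: int
    n_v: int
    pitch_u: float
    pitch_v: float
    angles: np.ndarray
    det_center_u: float | None = None
    det_center_v: float | None = None

    def __post_init__(self) -> None:
        if not (self.sad > 0):
            raise GeometryError("sad must be positive")
        if not (self.sdd >= self.sad):
            raise GeometryError("sdd must be >= sad")
        if self.n_u < 4 or self.n_v < 4:
            raise GeometryError("detector must be at least 4x4 pixels")
        if not (self.pitch_u > 0 and self.pitch_v > 0):
            raise GeometryError("pixel pitches must be positive")
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if angles.ndim != 1 or angles.size < 1:
            raise GeometryError("angles must be a non-empty 1-D sequence")
        object.__setattr__(self, "angles", angles)
        if self.det_center_u is None:
            object.__setattr__(self, "det_center_u", (self.n_u - 1) / 2.0)
        if self.det_center_v is None:
            object.__setattr__(self, "det_center_v", (self.n_v - 1) / 2.0)

    # -- derived quantities -------------------------------------------------

    @property
    def n_projections(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        """Panel magnification sdd / sad."""
        return self.sdd / self.sad

    @property
    def pitch_u_iso(self) -> float:
        """Detector pixel pitch rescaled to the isocenter plane (mm)."""
        return self.pitch_u * self.sad / self.sdd

    @property
    def pitch_v_iso(self) -> float:
        return self.pitch_v * self.sad / self.sdd

    # -- constructors / serialization --------------------------------------

    @classmethod
    def circular(
        cls,
        n_projections: int,
        *,
        sad: float = 1000.0,
        sdd: float = 1536.0,
        n_u: int = 96,
        n_v: int = 96,
        pitch_u: float = 1.6,
        pitch_v: float = 1.6,
        angle_start: float = 0.0,
        angle_range: float = 2.0 * np.pi,
        det_center_u: float | None = None,
        det_center_v: float | None = None,
    ) -> "ConeBeamGeometry":
        """Uniform full-scan geometry; defaults are the desk-scale study."""
        angles = angle_start + angle_range * np.arange(n_projections) / n_projections
        return cls(
            sad=sad, sdd=sdd, n_u=n_u, n_v=n_v,
            pitch_u=pitch_u, pitch_v=pitch_v, angles=angles,
            det_center_u=det_center_u, det_center_v=det_center_v,
        )

    def to_dict(self) -> dict:
        """Flat key-value block (assumes uniformly spaced angles)."""
        angles = self.angles
        start = float(np.degrees(angles[0]))
        if angles.size > 1:
            step = float(np.degrees(angles[1] - angles[0]))
            rng = step * angles.size
        else:
            rng = 360.0
        return {
            "sad_mm": float(self.sad),
            "sdd_mm": float(self.sdd),
            "n_u": int(self.n_u),
            "n_v": int(self.n_v),
            "pitch_u_mm": float(self.pitch_u),
            "pitch_v_mm": float(self.pitch_v),
            "det_center_u": float(self.det_center_u),
            "det_center_v": float(self.det_center_v),
            "n_projections": int(self.n_projections),
            "angle_start_deg": start,
            "angle_range_deg": float(rng),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConeBeamGeometry":
        return cls.circular(
            int(d["n_projections"]),
            sad=float(d["sad_mm"]),
            sdd=float(d["sdd_mm"]),
            n_u=int(d["n_u"]),
            n_v=int(d["n_v"]),
            pitch_u=float(d["pitch_u_mm"]),
            pitch_v=float(d["pitch_v_mm"]),
            angle_start=np.radians(float(d.get("angle_start_deg", 0.0))),
            angle_range=np.radians(float(d.get("angle_range_deg", 360.0))),
            det_center_u=float(d["det_center_u"]) if "det_center_u" in d else None,
            det_center_v=float(d["det_center_v"]) if "det_center_v" in d else None,
        )

    def source_position(self, theta: float) -> np.ndarray:
        """World-frame source position at gantry angle ``theta``."""
        d = self.sad
        return np.array([-d * np.sin(theta), -d * np.cos(theta), 0.0])

    def detector_pixel_position(self, theta: float, u_pix, v_pix) -> np.ndarray:
        """World-frame position of panel pixel centers ``(u_pix, v_pix)``.

        Accepts scalars or broadcastable arrays; returns shape ``(..., 3)``.
        """
        u_pix = np.asarray(u_pix, dtype=float)
        v_pix = np.asarray(v_pix, dtype=float)
        # gantry-frame panel coordinates
        gx = (u_pix - self.det_center_u) * self.pitch_u
        gy = np.broadcast_to(self.sdd - self.sad, gx.shape)
        gz = (v_pix - self.det_center_v) * self.pitch_v
        c, s = np.cos(theta), np.sin(theta)
        # inverse z-rotation takes gantry-frame points back to the world frame
        wx = c * gx + s * gy
        wy = -s * gx + c * gy
        wz = gz + np.zeros_like(gx)
        return np.stack([wx, wy, wz], axis=-1)


def rotate_to_gantry_frame(r, theta):
    """Rotate world coordinates ``r`` into the gantry frame at angle ``theta``.

    Applies the z-rotation ``(cos t * rx - sin t * ry, sin t * rx + cos t * ry, rz)``.
    ``r`` may be a single 3-vector or an array of shape ``(..., 3)``;
    ``theta`` broadcasts against the leading dimensions.
    """
    r = np.asarray(r, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    rx, ry, rz = r[..., 0], r[..., 1], r[..., 2]
    return np.stack([c * rx - s * ry, s * rx + c * ry, rz + np.zeros_like(c * rx)], axis=-1)


def project_to_detector(geom: ConeBeamGeometry, p):
    """Map gantry-frame points to continuous detector pixel coordinates.

    Returns ``(u_pix, v_pix)`` on the virtual isocenter-plane detector grid.
    Raises :class:`GeometryError` for points at or behind the source plane.
    """
    p = np.asarray(p, dtype=float)
    rx, ry, rz = p[..., 0], p[..., 1], p[..., 2]
    denom = geom.sad + ry
    if np.any(denom <= 0):
        raise GeometryError("point at or behind the source plane (sad + r_y <= 0)")
    u_iso = geom.sad * rx / denom
    v_iso = geom.sad * rz / denom
    u_pix = geom.det_center_u + u_iso / geom.pitch_u_iso
    v_pix = geom.det_center_v + v_iso / geom.pitch_v_iso
    return u_pix, v_pix


def depth_weight(geom: ConeBeamGeometry, p):
    """FDK depth weighting ``d^2 / (d + r_y)^2`` for gantry-frame points."""
    p = np.asarray(p, dtype=float)
    ry = p[..., 1]
    denom = geom.sad + ry
    if np.any(denom <= 0):
        raise GeometryError("point at or behind the source plane (sad + r_y <= 0)")
    return (geom.sad / denom) ** 2
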