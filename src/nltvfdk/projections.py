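"""Projection stack container shared by the simulator, denoisers and FDK chain."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ConeBeamGeometry

__all__ = ["ProjectionStack", "DomainError"]


class DomainError(ValueError):
    """Operation applied to a stack in the wrong domain (intensity vs log)."""


@dataclass
class ProjectionStack:
    """N cone-beam projections with per-projection gantry angle.

    ``values`` has shape ``(N, n_v, n_u)``.  ``domain`` is ``"log"`` for
    line integrals P = ln(I0/I) (dimensionless, mm^-1 times mm) or
    ``"intensity"`` for photon counts.  ``filtered`` marks stacks that have
    been ramp-filtered and are ready for backprojection.
    """

    values: np.ndarray
    geometry: ConeBeamGeometry
    domain: str = "log"
    filtered: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_projections, self.geometry.n_v, self.geometry.n_u)
        if v.shape != expected:
            raise ValueError(f"stack shape {v.shape} does not match geometry {expected}")
        if self.domain not in ("log", "intensity"):
            raise ValueError(f"unknown domain {self.domain!r}")
        self.values = v

    @property
    def n_projections(self) -> int:
        return self.values.shape[0]

    def require_domain(self, domain: str) -> None:
        if self.domain != domain:
            raise DomainError(f"expected a {domain}-domain stack, got {self.domain}")

    def with_values(self, values: np.ndarray, **changes) -> "ProjectionStack":
        """Copy of the stack with new pixel values (and optional tag changes)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)
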