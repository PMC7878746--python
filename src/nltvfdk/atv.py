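"""Local anisotropic-TV comparator arm.

A documented surrogate for the anisotropic-TV denoised FDK arm used for
ordering comparisons: a Perona-Malik edge-stopping map
c_j = exp(-(|grad P0_j| / k)^2) is computed once from the input
projection and used as a fixed local weight map in the same
normalized-gradient descent machinery as the non-local denoiser, i.e. it
minimizes sum_j c_j D(P_j).  Edges (large input gradient) get small
weights and are preserved; flat noisy regions are smoothed.  This module
is a baseline for qualitative error orderings, not a replication of any
specific published ATV variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nltv import NLTVParams, _descend, percentile_scale
from .projections import ProjectionStack

__all__ = ["ATVParams", "atv_denoise", "atv_denoise_stack", "edge_stopping_map"]


@dataclass(frozen=True)
class ATVParams:
    """Edge-stopping scale and descent controls of the local-TV baseline.

    ``k=None`` uses the 90th-percentile gradient-magnitude statistic of
    the input (same statistic as the non-local h0).
    """

    k: float | None = None
    k_percentile: float = 0.9
    n_iter: int = 10
    gamma0: float = 1.0
    r_red: float = 0.8
    delta: float = 1e-8
    max_reductions: int = 20

    def __post_init__(self) -> None:
        if self.k is not None and not (self.k > 0):
            raise ValueError("k must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def _descent_params(self) -> NLTVParams:
        return NLTVParams(
            n_iter=self.n_iter,
            gamma0=self.gamma0,
            r_red=self.r_red,
            delta=self.delta,
            max_reductions=self.max_reductions,
        )


def edge_stopping_map(P: np.ndarray, params: ATVParams | None = None) -> np.ndarray:
    """Perona-Malik weights exp(-(|grad P|/k)^2) from forward differences."""
    params = params or ATVParams()
    P = np.asarray(P, dtype=float)
    k = params.k
    if k is None:
        k = percentile_scale(P, "gradient", params.k_percentile, params.delta)
    k = max(float(k), params.delta)
    pu = np.pad(P, ((0, 0), (0, 1)), mode="edge")
    pv = np.pad(P, ((0, 1), (0, 0)), mode="edge")
    gu = pu[:, 1:] - P
    gv = pv[1:, :] - P
    mag2 = gu * gu + gv * gv
    return np.exp(-mag2 / (k * k))


def atv_denoise(P0: np.ndarray, params: ATVParams | None = None, return_trace: bool = False):
    """Denoise one projection by edge-stopped local TV descent."""
    params = params or ATVParams()
    P0 = np.asarray(P0, dtype=float)
    if not np.all(np.isfinite(P0)):
        raise ValueError("projection must be finite")
    c = edge_stopping_map(P0, params)
    P, trace = _descend(P0, c, params._descent_params())
    return (P, trace) if return_trace else P


def atv_denoise_stack(stack: ProjectionStack, params: ATVParams | None = None) -> ProjectionStack:
    """Apply the local-TV baseline to every projection of a log-domain stack."""
    stack.require_domain("log")
    params = params or ATVParams()
    out = np.empty_like(stack.values)
    for i in range(stack.n_projections):
        out[i] = atv_denoise(stack.values[i], params)
    return stack.with_values(out)
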