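import numpy as np
import pytest

from nltvfdk import (
    ConeBeamGeometry,
    NLTVParams,
    compute_weights,
    denoise_projection,
    denoise_stack,
    gaussian_patch_kernel,
    nltv_gradient,
    nltv_objective,
    percentile_scale,
    tv_magnitude,
)
from nltvfdk.projections import DomainError, ProjectionStack


class TestGaussianKernel:
    def test_normalized_and_peaked(self):
        k = gaussian_patch_kernel(2, 1.0)
        assert k.shape == (5, 5)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k[2, 2] == k.max()

    def test_symmetry(self):
        k = gaussian_patch_kernel(3, 1.7)
        assert np.allclose(k, k.T)
        assert np.allclose(k, k[::-1, :])
        assert np.allclose(k, k[:, ::-1])

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gaussian_patch_kernel(0, 1.0)
        with pytest.raises(ValueError):
            gaussian_patch_kernel(2, 0.0)


class TestPercentileScale:
    def test_constant_intensity(self):
        P = np.full((8, 8), 3.25)
        assert percentile_scale(P, "intensity", 0.5) == pytest.approx(3.25)

    def test_constant_gradient_returns_floor(self):
        P = np.full((8, 8), 3.25)
        assert percentile_scale(P, "gradient", 0.9, delta=1e-8) == pytest.approx(1e-8)

    def test_linear_ramp_unit_gradient(self):
        # ramp along u with unit step: every interior forward difference is 1
        P = np.tile(np.arange(32, dtype=float), (32, 1))
        assert percentile_scale(P, "gradient", 0.9) == pytest.approx(1.0)

    def test_empirical_quantile(self):
        P = np.arange(1.0, 101.0).reshape(10, 10)
        got = percentile_scale(P, "intensity", 0.9)
        assert got == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.9))
        assert abs(got - 90.0) < 1.0


def _weights_oracle(P, params, h0, tau):
    """Scalar double-loop transliteration of the non-local weight sum."""
    a, s = params.patch_half, params.search_half
    pad = a + s
    Pp = np.pad(P, pad, mode="reflect")
    kern = gaussian_patch_kernel(a, params.patch_sigma)
    ks = np.arange(-a, a + 1)
    nv, nu = P.shape
    # spatial factor on the Gaussian-patch local mean
    w = np.zeros_like(P)
    for jv in range(nv):
        for ju in range(nu):
            local = 0.0
            for kv in ks:
                for ku in ks:
                    local += kern[kv + a, ku + a] * Pp[pad + jv + kv, pad + ju + ku]
            spatial = (max(local, 0.0) / tau) ** params.epsilon
            acc = 0.0
            for dv in range(-s, s + 1):
                for du in range(-s, s + 1):
                    ssd = 0.0
                    for kv in ks:
                        for ku in ks:
                            d = (
                                Pp[pad + jv + kv, pad + ju + ku]
                                - Pp[pad + jv + dv + kv, pad + ju + du + ku]
                            )
                            ssd += kern[kv + a, ku + a] * d * d
                    acc += np.exp(-spatial * ssd / (2.0 * h0**2))
            w[jv, ju] = acc
    return w


class TestComputeWeights:
    def test_constant_projection_counts_search_sites(self):
        params = NLTVParams()
        P = np.full((30, 30), 2.0)
        w = compute_weights(P, params, h0=1.0, tau=1.0)
        assert np.allclose(w, 21 * 21, atol=1e-9)

    def test_matches_double_loop_oracle(self):
        params = NLTVParams(patch_half=1, search_half=1)
        rng = np.random.default_rng(5)
        P = rng.uniform(0.0, 2.0, size=(3, 3))
        h0, tau = 0.3, 1.1
        got = compute_weights(P, params, h0=h0, tau=tau)
        expect = _weights_oracle(P, params, h0, tau)
        assert np.allclose(got, expect, atol=1e-10)

    def test_matches_oracle_default_patch(self):
        params = NLTVParams(search_half=2)
        rng = np.random.default_rng(6)
        P = rng.uniform(0.0, 2.0, size=(6, 6))
        got = compute_weights(P, params, h0=0.4, tau=1.3)
        expect = _weights_oracle(P, params, 0.4, 1.3)
        assert np.allclose(got, expect, atol=1e-10)

    def test_higher_intensity_never_raises_weight(self):
        # raising the local intensity strengthens the spatial encoding
        # factor, which can only shrink the similarity terms
        params = NLTVParams(patch_half=1, search_half=1)
        rng = np.random.default_rng(7)
        P = rng.uniform(0.5, 1.5, size=(7, 7))
        w0 = compute_weights(P, params, h0=0.3, tau=1.0)
        P2 = P.copy()
        P2[3, 3] += 0.5
        w2 = compute_weights(P2, params, h0=0.3, tau=1.0)
        assert w2[3, 3] <= w0[3, 3] + 1e-12

    def test_rejects_non_finite(self):
        params = NLTVParams()
        P = np.zeros((8, 8))
        P[0, 0] = np.nan
        with pytest.raises(ValueError):
            compute_weights(P, params)


class TestTVMagnitude:
    def test_constant_gives_delta_floor(self):
        D = tv_magnitude(np.full((6, 6), 1.5), delta=1e-3)
        assert np.allclose(D, 1e-3)

    def test_unit_step_along_u(self):
        P = np.zeros((6, 6))
        P[:, 3:] = 1.0
        D = tv_magnitude(P, delta=1e-3)
        assert np.allclose(D[:, 3], np.sqrt(1.0 + 1e-6))
        assert np.allclose(D[:, 4], 1e-3)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(4, 4))
        delta = 1e-8
        D = tv_magnitude(P, delta)
        for v in range(4):
            for u in range(4):
                du = P[v, u] - P[v, u - 1] if u > 0 else 0.0
                dv = P[v, u] - P[v - 1, u] if v > 0 else 0.0
                assert D[v, u] == pytest.approx(
                    np.sqrt(du**2 + dv**2 + delta**2), abs=1e-12
                )


class TestObjectiveAndGradient:
    def test_objective_is_weighted_sum_of_magnitudes(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(9, 9))
        w = rng.uniform(1.0, 5.0, size=(9, 9))
        assert nltv_objective(P, w) == pytest.approx(
            float((w * tv_magnitude(P)).sum()), rel=1e-12
        )

    def test_constant_projection_floor(self):
        w = np.full((10, 10), 3.0)
        got = nltv_objective(np.full((10, 10), 7.0), w, delta=1e-4)
        assert got == pytest.approx(100 * 3.0 * 1e-4, rel=1e-9)

    def test_near_homogeneity_in_scale(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(8, 8))
        w = rng.uniform(1.0, 2.0, size=(8, 8))
        delta = 1e-12
        r1 = nltv_objective(P, w, delta)
        r3 = nltv_objective(3.0 * P, w, delta)
        assert r3 == pytest.approx(3.0 * r1, rel=1e-9)

    def test_gradient_of_constant_is_zero(self):
        w = np.ones((8, 8))
        g, n = nltv_gradient(np.full((8, 8), 2.0), w)
        assert np.all(g == 0)
        assert n == 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        delta = 1e-3  # large enough to keep the objective smooth for FD
        for _ in range(3):
            P = rng.normal(size=(5, 5))
            w = rng.uniform(0.5, 3.0, size=(5, 5))
            g, n = nltv_gradient(P, w, delta)
            h = 1e-6
            num = np.zeros_like(P)
            for v in range(5):
                for u in range(5):
                    Pp = P.copy()
                    Pp[v, u] += h
                    Pm = P.copy()
                    Pm[v, u] -= h
                    num[v, u] = (
                        nltv_objective(Pp, w, delta) - nltv_objective(Pm, w, delta)
                    ) / (2 * h)
            assert np.allclose(g, num, rtol=1e-4, atol=1e-7)
            assert n == pytest.approx(np.sqrt((g**2).sum()), rel=1e-12)

    def test_reduces_to_local_tv_gradient_with_unit_weights(self):
        # independent local-TV gradient written directly from the
        # stabilized backward-difference objective
        rng = np.random.default_rng(12)
        P = rng.normal(size=(7, 7))
        delta = 1e-6

        def local_tv_grad(P):
            n_v, n_u = P.shape
            g = np.zeros_like(P)
            def D(v, u):
                du = P[v, u] - P[v, u - 1] if u > 0 else 0.0
                dv = P[v, u] - P[v - 1, u] if v > 0 else 0.0
                return np.sqrt(du * du + dv * dv + delta * delta)
            for v in range(n_v):
                for u in range(n_u):
                    du = P[v, u] - P[v, u - 1] if u > 0 else 0.0
                    dv = P[v, u] - P[v - 1, u] if v > 0 else 0.0
                    g[v, u] += (du + dv) / D(v, u)
                    if u + 1 < n_u:
                        g[v, u] -= (P[v, u + 1] - P[v, u]) / D(v, u + 1)
                    if v + 1 < n_v:
                        g[v, u] -= (P[v + 1, u] - P[v, u]) / D(v + 1, u)
            return g

        got, _ = nltv_gradient(P, np.ones_like(P), delta)
        assert np.allclose(got, local_tv_grad(P), atol=1e-10)


class TestDenoiseProjection:
    def test_constant_returned_unchanged(self):
        P = np.full((16, 16), 1.3)
        out, trace = denoise_projection(P, NLTVParams(), return_trace=True)
        assert np.array_equal(out, P)
        assert len(trace) == 1  # zero gradient: no accepted steps

    def test_impulse_shrinks(self):
        P = np.ones((16, 16))
        P[8, 8] = 2.0
        out = denoise_projection(P, NLTVParams())
        assert abs(out[8, 8] - np.median(out)) < 1.0 - 1e-6

    def test_objective_trace_non_increasing(self):
        # stationary objective: weights computed once from the input
        rng = np.random.default_rng(21)
        params = NLTVParams(recompute_weights=False)
        for _ in range(5):
            P = np.clip(rng.normal(1.0, 0.2, size=(24, 24)), 0.0, None)
            _, trace = denoise_projection(P, params, return_trace=True)
            assert len(trace) >= 2
            assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_shift_equivariance_of_embedded_feature(self):
        # a compact noisy feature on a constant background, translated far
        # from the borders: the value and gradient histograms (hence h0 and
        # tau) are identical, so denoising must commute with the shift
        rng = np.random.default_rng(22)
        feature = rng.normal(1.0, 0.1, size=(12, 12)).clip(0.0, None)
        base = np.ones((40, 40))
        shifted = np.ones((40, 40))
        base[14:26, 13:25] = feature
        shifted[14:26, 16:28] = feature
        params = NLTVParams(n_iter=3)
        d0 = denoise_projection(base, params)
        d1 = denoise_projection(shifted, params)
        assert np.allclose(d0[14:26, 13:25], d1[14:26, 16:28], atol=1e-6)

    def test_non_finite_input_rejected(self):
        P = np.ones((8, 8))
        P[2, 2] = np.inf
        with pytest.raises(ValueError):
            denoise_projection(P, NLTVParams())


class TestDenoiseStack:
    def _noisy_stack(self, n=3, seed=31):
        geom = ConeBeamGeometry.circular(n, n_u=24, n_v=24, pitch_u=6.0, pitch_v=6.0)
        rng = np.random.default_rng(seed)
        vals = np.clip(rng.normal(1.0, 0.15, size=(n, 24, 24)), 0.0, None)
        return ProjectionStack(vals, geom, domain="log")

    def test_single_projection_matches_denoise_projection(self):
        stack = self._noisy_stack(n=1)
        params = NLTVParams(n_iter=2)
        out = denoise_stack(stack, params)
        direct = denoise_projection(stack.values[0], params)
        assert np.array_equal(out.values[0], direct)

    def test_projections_processed_independently(self):
        stack = self._noisy_stack(n=3)
        params = NLTVParams(n_iter=2)
        out = denoise_stack(stack, params)
        perm = [2, 0, 1]
        permuted = stack.with_values(stack.values[perm])
        out_perm = denoise_stack(permuted, params)
        assert np.array_equal(out_perm.values, out.values[perm])

    def test_variance_reduced_on_noisy_stack(self):
        stack = self._noisy_stack(n=3)
        out = denoise_stack(stack, NLTVParams())
        var_in = stack.values.var(axis=(1, 2)).mean()
        var_out = out.values.var(axis=(1, 2)).mean()
        assert var_out < var_in

    def test_requires_log_domain(self):
        stack = self._noisy_stack(n=1)
        bad = stack.with_values(np.exp(-stack.values) * 100, domain="intensity")
        with pytest.raises(DomainError):
            denoise_stack(bad)


def test_params_validation():
    with pytest.raises(ValueError):
        NLTVParams(patch_half=0)
    with pytest.raises(ValueError):
        NLTVParams(search_half=1)  # < patch_half default 2
    with pytest.raises(ValueError):
        NLTVParams(h0_percentile=1.5)
    with pytest.raises(ValueError):
        NLTVParams(r_red=1.0)
    with pytest.raises(ValueError):
        NLTVParams(epsilon=0.5)
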