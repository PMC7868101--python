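import numpy as np
import pytest

from sosperf import (
    DynamicVolume,
    ReconConfig,
    build_pattern,
    forward,
    gridding_recon,
    lcurve_select,
    simulate_coils,
    stcr_cost,
    stcr_reconstruct,
)
from sosperf.encoding import KSpaceSeries, StackOfStarsEncoder
from sosperf.recon import menger_curvature


@pytest.fixture(scope="module")
def full_sampling_setup(smooth_static_volume):
    """Fully sampled (spokes >= pi/2 * n) smooth static object."""
    vol = smooth_static_volume
    T, nz, n, _ = vol.data.shape
    pattern = build_pattern(
        n_readout=2 * n, n_spokes_per_frame=51, n_frames=T, n_partitions=nz
    )
    coils = simulate_coils((nz, n, n), 4, seed=11)
    ks = forward(vol, coils, pattern, backend="nufft")
    return vol, pattern, coils, ks


class TestGriddingRecon:
    def test_zero_data_gives_zero_image(self, full_sampling_setup):
        vol, pattern, coils, ks = full_sampling_setup
        zero = KSpaceSeries(np.zeros_like(ks.data), pattern)
        out = gridding_recon(zero, coils, pattern)
        assert np.allclose(out.data, 0)

    def test_fully_sampled_nrmse(self, full_sampling_setup):
        vol, pattern, coils, ks = full_sampling_setup
        out = gridding_recon(ks, coils, pattern)
        nrmse = np.linalg.norm(out.data - vol.data) / np.linalg.norm(vol.data)
        assert nrmse <= 0.05

    def test_unit_object_scale(self, full_sampling_setup):
        """Density-compensated adjoint is normalised to object scale."""
        vol, pattern, coils, ks = full_sampling_setup
        out = gridding_recon(ks, coils, pattern)
        assert np.abs(out.data).max() == pytest.approx(
            np.abs(vol.data).max(), rel=0.1
        )

    def test_linearity(self, full_sampling_setup, rng):
        vol, pattern, coils, ks = full_sampling_setup
        d2 = rng.standard_normal(ks.data.shape) + 1j * rng.standard_normal(ks.data.shape)
        a, b = 1.5 - 0.5j, -2.0 + 1j
        combo = KSpaceSeries(a * ks.data + b * d2, pattern)
        lhs = gridding_recon(combo, coils, pattern).data
        rhs = a * gridding_recon(ks, coils, pattern).data + b * gridding_recon(
            KSpaceSeries(d2, pattern), coils, pattern
        ).data
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) <= 1e-9

    def test_rss_combine_option(self, full_sampling_setup):
        vol, pattern, coils, ks = full_sampling_setup
        out = gridding_recon(ks, coils, pattern, combine="rss")
        assert np.all(np.isreal(out.data))


@pytest.fixture(scope="module")
def instance(rng):
    pattern = build_pattern(
        n_readout=16, n_spokes_per_frame=4, n_frames=3, n_partitions=2
    )
    n = pattern.grid_size  # 8
    coils = simulate_coils((2, n, n), 2, seed=1)
    truth = rng.standard_normal((3, 2, n, n)) + 1j * rng.standard_normal((3, 2, n, n))
    enc = StackOfStarsEncoder(pattern, backend="dft")
    data = KSpaceSeries(enc.forward_data(truth, coils), pattern)
    return pattern, coils, truth, data


class TestStcrCost:
    def test_fidelity_only_limit(self, instance, rng):
        pattern, coils, truth, data = instance
        m = rng.standard_normal(truth.shape) + 1j * rng.standard_normal(truth.shape)
        cfg = ReconConfig(alpha_t=0, alpha_s=0, backend="dft")
        cost, _ = stcr_cost(m, data, coils, pattern, cfg)
        enc = StackOfStarsEncoder(pattern, backend="dft")
        resid = enc.forward_data(m, coils) - data.data
        assert cost == pytest.approx(np.sum(np.abs(resid) ** 2), rel=1e-12)

    def test_gradient_matches_finite_differences(self, instance, rng):
        """Analytic gradient vs central differences on an 8x8x2x3 instance."""
        pattern, coils, truth, data = instance
        cfg = ReconConfig(alpha_t=0.7, alpha_s=0.3, epsilon=0.05, backend="dft")
        m = rng.standard_normal(truth.shape) + 1j * rng.standard_normal(truth.shape)
        _, grad = stcr_cost(m, data, coils, pattern, cfg)
        h = 1e-6
        worst = 0.0
        idx = [tuple(rng.integers(0, s) for s in m.shape) for _ in range(8)]
        for i in idx:
            for val in (1.0, 1j):
                mp = m.copy(); mp[i] += h * val
                mm = m.copy(); mm[i] -= h * val
                jp, _ = stcr_cost(mp, data, coils, pattern, cfg)
                jm, _ = stcr_cost(mm, data, coils, pattern, cfg)
                fd = (jp - jm) / (2 * h)
                an = grad[i].real if val == 1.0 else grad[i].imag
                worst = max(worst, abs(fd - an) / max(abs(fd), 1e-12))
        assert worst <= 1e-6

    def test_exact_solution_zero_cost(self, instance):
        pattern, coils, truth, data = instance
        cfg = ReconConfig(alpha_t=0, alpha_s=0, backend="dft")
        cost, _ = stcr_cost(truth, data, coils, pattern, cfg)
        assert cost <= 1e-18 * np.sum(np.abs(data.data) ** 2)


class TestStcrReconstruct:
    def test_converges_fully_sampled_alphas_zero(self, full_sampling_setup):
        vol, pattern, coils, ks = full_sampling_setup
        cfg = ReconConfig(alpha_t=0, alpha_s=0, max_iter=50, tol=0)
        rec, trace = stcr_reconstruct(ks, coils, pattern, cfg)
        nrmse = np.linalg.norm(rec.data - vol.data) / np.linalg.norm(vol.data)
        assert nrmse <= 0.05
        assert all(trace[i + 1] <= trace[i] + 1e-12 for i in range(len(trace) - 1))

    def test_gradient_norm_decreases_with_iterations(self, full_sampling_setup):
        vol, pattern, coils, ks = full_sampling_setup
        enc = StackOfStarsEncoder(pattern, backend="nufft")
        norms = []
        for it in (5, 25, 60):
            cfg = ReconConfig(alpha_t=0, alpha_s=0, max_iter=it, tol=0)
            rec, _ = stcr_reconstruct(ks, coils, pattern, cfg)
            resid = enc.forward_data(rec.data, coils) - ks.data
            norms.append(np.linalg.norm(enc.adjoint_data(resid, coils)))
        assert norms[0] > norms[1] > norms[2]

    def test_temporal_regularisation_reduces_frame_noise(self, smooth_static_volume):
        """Static object, 8x angular undersampling: STCR output varies less
        across frames than gridding of the same data."""
        vol = smooth_static_volume
        T, nz, n, _ = vol.data.shape
        pattern = build_pattern(
            n_readout=2 * n, n_spokes_per_frame=6, n_frames=T, n_partitions=nz
        )
        coils = simulate_coils((nz, n, n), 4, seed=11)
        clean = forward(vol, coils, pattern)
        sd = float(np.median(np.abs(clean.data)))
        ks = forward(vol, coils, pattern, noise_sd=sd, seed=13)
        g = gridding_recon(ks, coils, pattern)
        rec, _ = stcr_reconstruct(
            ks, coils, pattern, ReconConfig(max_iter=60, tol=0)
        )
        mask = np.abs(vol.data[0, 1]) > 0.3
        g_series = np.array([np.abs(g.data[f, 1][mask]).mean() for f in range(T)])
        r_series = np.array([np.abs(rec.data[f, 1][mask]).mean() for f in range(T)])
        assert r_series.std() < g_series.std()

    def test_no_new_temporal_extrema_in_denoising(self):
        """Temporal TV does not push voxel time series outside the data range
        (plus the noise level) on a smooth, fully sampled instance."""
        n, nz, T = 16, 1, 6
        y, x = np.mgrid[0:n, 0:n]
        blob = np.exp(-(((x - 8) / 4.0) ** 2 + ((y - 8) / 4.0) ** 2))
        ramp = np.linspace(1.0, 2.0, T)
        data = np.stack([blob * r for r in ramp])[:, None]
        vol = DynamicVolume(data.astype(complex))
        pattern = build_pattern(
            n_readout=32, n_spokes_per_frame=26, n_frames=T, n_partitions=1
        )
        coils = simulate_coils((1, n, n), 1)
        sd = 0.05 * float(np.median(np.abs(forward(vol, coils, pattern).data)))
        ks = forward(vol, coils, pattern, noise_sd=sd, seed=3)
        rec, _ = stcr_reconstruct(
            ks, coils, pattern, ReconConfig(alpha_t=0.05, max_iter=80, tol=0)
        )
        series = np.abs(rec.data[:, 0])
        truth = np.abs(vol.data[:, 0])
        lo = truth.min(axis=0) - 0.1 * truth.max()
        hi = truth.max(axis=0) + 0.1 * truth.max()
        assert np.all(series >= lo - 1e-9) and np.all(series <= hi + 1e-9)


@pytest.fixture(scope="module")
def noisy_setup():
    """Static ringed object, 8 frames, undersampled and noisy: the
    temporal TV penalty is then the dominant, alpha-sensitive term."""
    n, nz, T = 32, 2, 8
    y, x = np.mgrid[0:n, 0:n]
    r = np.sqrt((x - n // 2) ** 2 + (y - n // 2) ** 2)
    obj = 0.8 * np.exp(-((r / 10) ** 2)) + 0.4 * ((r > 5) & (r < 9))
    vol = DynamicVolume(np.broadcast_to(obj, (T, nz, n, n)).astype(complex).copy())
    pattern = build_pattern(
        n_readout=2 * n, n_spokes_per_frame=6, n_frames=T, n_partitions=nz
    )
    coils = simulate_coils((nz, n, n), 4, seed=7)
    sd = float(np.median(np.abs(forward(vol, coils, pattern).data)))
    ks = forward(vol, coils, pattern, noise_sd=sd, seed=7)
    return pattern, coils, ks


class TestLCurve:
    def test_single_point_grid_returns_it(self, noisy_setup):
        pattern, coils, ks = noisy_setup
        alpha, diag = lcurve_select(
            ks, coils, pattern, alpha_grid=[0.02], config=ReconConfig(max_iter=5)
        )
        assert alpha == 0.02
        assert diag["residual_norms"].size == 1

    def test_monotone_trade_off_and_corner_oracle(self, noisy_setup):
        pattern, coils, ks = noisy_setup
        grid = (0.005, 0.01, 0.02, 0.04, 0.08)
        alpha, diag = lcurve_select(
            ks, coils, pattern, alpha_grid=grid,
            config=ReconConfig(max_iter=300, tol=0, epsilon=1e-3),
        )
        r, p = diag["residual_norms"], diag["penalty_norms"]
        assert np.all(np.diff(r) >= 0), "residual must not decrease with alpha"
        assert np.all(np.diff(p) <= 0), "penalty must not increase with alpha"
        # independent three-point circumradius curvature oracle
        pts = np.column_stack([np.log(r), np.log(p)])
        kap = np.zeros(len(grid))
        for i in range(1, len(grid) - 1):
            a, b, c = pts[i - 1], pts[i], pts[i + 1]
            la, lb, lc = (
                np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(c - a)
            )
            s = 0.5 * (la + lb + lc)
            area = np.sqrt(max(s * (s - la) * (s - lb) * (s - lc), 0.0))
            kap[i] = 4.0 * area / (la * lb * lc) if la * lb * lc > 0 else 0.0
        assert alpha == grid[int(np.argmax(kap))]

    def test_invalid_grids_rejected(self, noisy_setup):
        pattern, coils, ks = noisy_setup
        with pytest.raises(ValueError):
            lcurve_select(ks, coils, pattern, alpha_grid=[])
        with pytest.raises(ValueError):
            lcurve_select(ks, coils, pattern, alpha_grid=[0.1, np.nan])
        with pytest.raises(ValueError):
            lcurve_select(ks, coils, pattern, alpha_grid=[0.2, 0.1])


def test_menger_curvature_of_right_angle():
    # circumcircle through three corners of a unit right angle has radius
    # sqrt(2)/2, hence curvature sqrt(2)
    pts = np.array([[0.0, 1.0], [0.0, 0.0], [1.0, 0.0]])
    kap = menger_curvature(pts)
    assert kap[1] == pytest.approx(np.sqrt(2.0), rel=1e-12)
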