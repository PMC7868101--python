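import numpy as np
import pytest

from sosperf import (
    DynamicVolume,
    PhantomSpec,
    build_pattern,
    forward,
    render_dynamic_phantom,
    simulate_coils,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pattern():
    """16x16 grid, 2 frames, 4 partitions, 6 spokes/frame."""
    return build_pattern(n_readout=32, n_spokes_per_frame=6, n_frames=2, n_partitions=4)


@pytest.fixture(scope="session")
def small_coils(small_pattern):
    n = small_pattern.grid_size
    return simulate_coils((small_pattern.n_partitions, n, n), 2, seed=3)


@pytest.fixture(scope="session")
def small_volume(small_pattern, rng):
    n = small_pattern.grid_size
    shape = (small_pattern.n_frames, small_pattern.n_partitions, n, n)
    data = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return DynamicVolume(data)


@pytest.fixture(scope="session")
def smooth_static_volume():
    """Smooth Gaussian object, constant across 3 frames (32x32x4)."""
    n, nz, T = 32, 4, 3
    y, x = np.mgrid[0:n, 0:n]
    blob = np.exp(-(((x - n // 2) / 8.0) ** 2 + ((y - n // 2) / 8.0) ** 2))
    data = np.broadcast_to(blob, (T, nz, n, n)).astype(complex).copy()
    return DynamicVolume(data)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Quick 32x32x4 dynamic phantom with a transmural defect."""
    from sosperf import DefectSpec, LVGeometry

    spec = PhantomSpec(
        nx=32, ny=32, nz=4,
        voxel_mm=(5.0, 5.0, 10.0),
        lv=LVGeometry(endo_radius=25.0, epi_radius=45.0, long_axis_extent=70.0),
        defects=[DefectSpec(angle_start_deg=150, angle_span_deg=80,
                            partition_lo=1, partition_hi=2,
                            transmural_fraction=1.0, flow_reduction=0.6)],
        n_frames=16,
        seed=9,
    )
    vol, gt = render_dynamic_phantom(spec)
    return spec, vol, gt
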