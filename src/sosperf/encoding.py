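"""Multicoil stack-of-stars encoding operators.

The forward model maps a dynamic volume ``m`` to multicoil k-space data

    d[c, f, p, s, r] = NUFFT2{ FFT_z{ S_c * m[f] } }(k_{f,s,r})

i.e. per frame: multiply by each coil sensitivity, Cartesian FFT along
the partition (kz) axis, then in-plane nonuniform Fourier sampling at
that frame's spokes.  ``adjoint`` is the exact conjugate transpose.

Partition index ``p`` holds the centred kz frequency ``p - nz//2``; the
acquisition-time ordering of partitions (``pattern.kz_order``) affects
shot timing only, not sample values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DynamicVolume
from .nufft import make_plan
from .sampling import SamplingPattern


@dataclass
class CoilProfile:
    """Complex coil sensitivity maps, shape (n_coils, nz, ny, nx)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("coil maps must have shape (n_coils, nz, ny, nx)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class KSpaceSeries:
    """Multicoil non-Cartesian raw data paired with its sampling pattern.

    data shape: (n_coils, n_frames, n_partitions, n_spokes_per_frame, n_readout).
    """

    data: np.ndarray
    pattern: SamplingPattern
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        p = self.pattern
        expected = (
            self.data.shape[0],
            p.n_frames,
            p.n_partitions,
            p.n_spokes_per_frame,
            p.n_readout,
        )
        if self.data.shape != expected:
            raise ValueError(
                f"k-space shape {self.data.shape} inconsistent with pattern {expected[1:]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space contains non-finite values")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]


def simulate_coils(
    grid: tuple[int, int, int], n_coils: int, seed: int = 0
) -> CoilProfile:
    """Smooth synthetic coil maps: Gaussian bumps placed around the FOV.

    ``n_coils == 1`` returns the uniform all-ones map.  Each coil is a
    broad Gaussian centred outside the object on a ring, with a smooth
    linear phase; a small uniform floor keeps the root-sum-of-squares
    strictly positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nz, ny, nx = grid
    if n_coils == 1:
        return CoilProfile(np.ones((1, nz, ny, nx), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    z, y, x = np.meshgrid(
        np.arange(nz) - nz / 2.0,
        np.arange(ny) - ny / 2.0,
        np.arange(nx) - nx / 2.0,
        indexing="ij",
    )
    maps = np.empty((n_coils, nz, ny, nx), dtype=np.complex128)
    radius = 0.6 * max(nx, ny)
    width = 0.7 * max(nx, ny)
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cy, cx = radius * np.sin(theta), radius * np.cos(theta)
        cz = rng.normal(0, 0.1) * nz
        mag = np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2 + ((z - cz) * 2.0) ** 2) / (2 * width**2)
        )
        phase = (
            rng.normal(0, 0.5)
            + rng.normal(0, 0.02) * x
            + rng.normal(0, 0.02) * y
            + rng.normal(0, 0.02) * z
        )
        maps[c] = (0.05 + mag) * np.exp(1j * phase)
    return CoilProfile(maps)


class StackOfStarsEncoder:
    """Precomputed forward/adjoint encoding for one pattern + grid + backend.

    Builds one in-plane NUFFT (or direct-DFT) plan per frame and reuses it
    across coils, partitions and iterations.
    """

    def __init__(self, pattern: SamplingPattern, backend: str = "nufft", **plan_kwargs):
        self.pattern = pattern
        self.backend = backend
        self.n = pattern.grid_size
        self._plans = []
        for f in range(pattern.n_frames):
            kx, ky = pattern.spoke_coordinates(f)
            self._plans.append(
                make_plan(kx.ravel(), ky.ravel(), self.n, backend=backend, **plan_kwargs)
            )

    # z-axis centred FFT pair (unnormalised forward; adjoint = ifft * nz)
    @staticmethod
    def _fft_z(x: np.ndarray) -> np.ndarray:
        return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(x, axes=1), axis=1), axes=1)

    @staticmethod
    def _adj_fft_z(x: np.ndarray) -> np.ndarray:
        nz = x.shape[1]
        return (
            np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(x, axes=1), axis=1), axes=1) * nz
        )

    def _check(self, volume_data: np.ndarray, coils: CoilProfile) -> None:
        p = self.pattern
        nz = p.n_partitions
        if volume_data.shape[1:] != (nz, self.n, self.n):
            raise ValueError(
                f"volume grid {volume_data.shape[1:]} inconsistent with pattern "
                f"({nz}, {self.n}, {self.n})"
            )
        if coils.maps.shape[1:] != (nz, self.n, self.n):
            raise ValueError("coil maps inconsistent with pattern grid")

    def forward_data(self, volume_data: np.ndarray, coils: CoilProfile) -> np.ndarray:
        """Volume data (frames, nz, ny, nx) -> samples (coils, frames, nz, spokes, readout)."""
        self._check(volume_data, coils)
        p = self.pattern
        nc = coils.n_coils
        out = np.empty(
            (nc, p.n_frames, p.n_partitions, p.n_spokes_per_frame, p.n_readout),
            dtype=np.complex128,
        )
        for f in range(p.n_frames):
            coil_imgs = coils.maps * volume_data[f][None]  # (nc, nz, ny, nx)
            kz = self._fft_z(coil_imgs)
            samples = self._plans[f].forward(kz.reshape(nc * p.n_partitions, self.n, self.n))
            out[:, f] = samples.reshape(nc, p.n_partitions, p.n_spokes_per_frame, p.n_readout)
        return out

    def adjoint_data(
        self,
        samples: np.ndarray,
        coils: CoilProfile,
        weights: np.ndarray | None = None,
        per_coil: bool = False,
    ) -> np.ndarray:
        """Samples -> volume data (frames, nz, ny, nx); conjugate transpose of forward.

        ``weights`` (spokes, readout) pre-multiplies samples (density
        compensation).  With ``per_coil`` the conjugate-coil combination is
        skipped and (coils, frames, nz, ny, nx) is returned.
        """
        p = self.pattern
        nc = samples.shape[0]
        if coils.n_coils != nc:
            raise ValueError("coil count mismatch between samples and maps")
        out_pc = np.empty(
            (nc, p.n_frames, p.n_partitions, self.n, self.n), dtype=np.complex128
        )
        for f in range(p.n_frames):
            s = samples[:, f]
            if weights is not None:
                s = s * weights[None, None]
            flat = s.reshape(nc * p.n_partitions, -1)
            imgs = self._plans[f].adjoint(flat).reshape(
                nc, p.n_partitions, self.n, self.n
            )
            out_pc[:, f] = self._adj_fft_z(imgs)
        if per_coil:
            return out_pc
        return np.sum(np.conj(coils.maps)[:, None] * out_pc, axis=0)


_ENCODER_CACHE: dict[tuple, StackOfStarsEncoder] = {}


def _pattern_key(pattern: SamplingPattern, backend: str) -> tuple:
    return (
        backend,
        pattern.n_readout,
        pattern.n_spokes_per_frame,
        pattern.n_frames,
        pattern.n_partitions,
        pattern.readout_oversampling,
        pattern.angle_schedule.tobytes(),
    )


def get_encoder(pattern: SamplingPattern, backend: str = "nufft") -> StackOfStarsEncoder:
    """Cached encoder lookup (plans are expensive to rebuild every call)."""
    key = _pattern_key(pattern, backend)
    if key not in _ENCODER_CACHE:
        if len(_ENCODER_CACHE) > 8:
            _ENCODER_CACHE.clear()
        _ENCODER_CACHE[key] = StackOfStarsEncoder(pattern, backend=backend)
    return _ENCODER_CACHE[key]


def forward(
    volume: DynamicVolume,
    coils: CoilProfile,
    pattern: SamplingPattern,
    noise_sd: float = 0.0,
    seed: int | None = None,
    backend: str = "nufft",
) -> KSpaceSeries:
    """Simulate multicoil stack-of-stars k-space from a dynamic volume.

    Circular complex Gaussian receiver noise of standard deviation
    ``noise_sd`` (per real/imag channel) is added when ``noise_sd > 0``.
    """
    enc = get_encoder(pattern, backend)
    data = enc.forward_data(volume.data, coils)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return KSpaceSeries(data=data, pattern=pattern, noise_sd=float(noise_sd))


def adjoint(
    data: KSpaceSeries,
    coils: CoilProfile,
    pattern: SamplingPattern | None = None,
    weights: np.ndarray | None = None,
    backend: str = "nufft",
) -> DynamicVolume:
    """Conjugate-transpose encoding: k-space samples -> dynamic volume.

    With ``weights`` this is the density-compensated (gridding) adjoint.
    """
    pattern = pattern or data.pattern
    enc = get_encoder(pattern, backend)
    vol = enc.adjoint_data(data.data, coils, weights=weights)
    return DynamicVolume(data=vol, provenance="gridding")
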