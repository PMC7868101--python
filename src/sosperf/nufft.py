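"""In-plane nonuniform Fourier transforms for radial sampling.

Two interchangeable backends evaluate

    type-2 (forward):  F_j = sum_x m[x] exp(-2*pi*i k_j . x)
    type-1 (adjoint):  m[x] = sum_j F_j  exp(+2*pi*i k_j . x)

for an ``n x n`` image with centre-origin indices ``x in [-n/2, n/2)`` and
normalised frequencies ``k in [-0.5, 0.5)`` cycles/pixel:

* :class:`DirectDft2` — exact direct summation; the oracle, O(n^2 M),
  intended for grids up to ~32^2;
* :class:`KaiserBesselNufft2` — gridding NUFFT: Kaiser-Bessel
  interpolation on a 2x oversampled FFT grid with analytic deapodisation.
  Kernel width 7 with the Beatty beta reaches ~1e-6 relative agreement
  with the direct transform.

Both operate on batches: input shape ``(..., n, n)`` maps to samples
``(..., M)`` and back.  The adjoint is the exact conjugate transpose of the
forward within each backend.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class DirectDft2:
    """Exact direct-summation nonuniform DFT (the small-grid oracle)."""

    def __init__(self, kx: np.ndarray, ky: np.ndarray, n: int):
        kx = np.asarray(kx, dtype=float).ravel()
        ky = np.asarray(ky, dtype=float).ravel()
        self.n = int(n)
        self.n_samples = kx.size
        x = np.arange(n) - n // 2
        # E has shape (M, n*n): F = E @ m.ravel()
        phase_x = np.exp(-2j * np.pi * kx[:, None] * x[None, :])
        phase_y = np.exp(-2j * np.pi * ky[:, None] * x[None, :])
        self._E = (phase_y[:, :, None] * phase_x[:, None, :]).reshape(kx.size, n * n)

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        batch = image.shape[:-2]
        flat = image.reshape(-1, self.n * self.n)
        out = flat @ self._E.T
        return out.reshape(*batch, self.n_samples)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        samples = np.asarray(samples)
        batch = samples.shape[:-1]
        flat = samples.reshape(-1, self.n_samples)
        out = flat @ np.conj(self._E)
        return out.reshape(*batch, self.n, self.n)


def _kaiser_bessel(t: np.ndarray, width: int, beta: float) -> np.ndarray:
    """KB interpolation kernel on |t| <= width/2, zero outside."""
    arg = 1.0 - (2.0 * t / width) ** 2
    out = np.zeros_like(t, dtype=float)
    ok = arg > 0
    out[ok] = np.i0(beta * np.sqrt(arg[ok]))
    return out


def _kb_fourier(f: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the KB kernel at frequency ``f``.

    integral_{-W/2}^{W/2} kb(t) exp(2*pi*i*f*t) dt
      = W * sinh(sqrt(beta^2 - s^2)) / sqrt(beta^2 - s^2),  s = pi*W*f,
    continued with sin for s > beta.
    """
    s = np.pi * width * np.asarray(f, dtype=float)
    d = beta**2 - s**2
    out = np.empty_like(s)
    pos = d > 0
    rt = np.sqrt(np.abs(d))
    out[pos] = np.sinh(rt[pos]) / rt[pos]
    out[~pos] = np.sinc(rt[~pos] / np.pi)  # sin(rt)/rt
    return width * out


class KaiserBesselNufft2:
    """Gridding NUFFT with precomputed sparse interpolation.

    Parameters
    ----------
    kx, ky : arrays of normalised frequencies in [-0.5, 0.5).
    n : image size (square grid).
    oversampling : grid oversampling factor sigma (default 2).
    width : kernel width in oversampled grid cells (default 7).
    """

    def __init__(
        self,
        kx: np.ndarray,
        ky: np.ndarray,
        n: int,
        oversampling: float = 2.0,
        width: int = 7,
    ):
        kx = np.asarray(kx, dtype=float).ravel()
        ky = np.asarray(ky, dtype=float).ravel()
        self.n = int(n)
        self.n_samples = kx.size
        self.ng = int(round(oversampling * n))
        self.width = int(width)
        sigma = self.ng / n
        # Beatty et al. choice of beta for given width and oversampling.
        self.beta = np.pi * np.sqrt(
            (width / sigma) ** 2 * (sigma - 0.5) ** 2 - 0.8
        )
        self._interp = self._build_interp(kx, ky)
        self._deapod = self._build_deapod()

    def _build_interp(self, kx: np.ndarray, ky: np.ndarray) -> sp.csr_matrix:
        ng, w = self.ng, self.width
        # continuous oversampled-grid frequency of each sample
        qx = kx * ng
        qy = ky * ng
        offs = np.arange(w)
        jx0 = np.ceil(qx - w / 2.0).astype(int)
        jy0 = np.ceil(qy - w / 2.0).astype(int)
        wx = _kaiser_bessel(qx[:, None] - (jx0[:, None] + offs[None, :]), w, self.beta)
        wy = _kaiser_bessel(qy[:, None] - (jy0[:, None] + offs[None, :]), w, self.beta)
        # grid index with wraparound; spectrum kept in unshifted FFT layout
        # (frequency q lives at index q mod ng), so no fftshift is needed
        gx = np.mod(jx0[:, None] + offs[None, :], ng)
        gy = np.mod(jy0[:, None] + offs[None, :], ng)
        vals = (wy[:, :, None] * wx[:, None, :]).reshape(self.n_samples, -1)
        cols = (gy[:, :, None] * ng + gx[:, None, :]).reshape(self.n_samples, -1)
        rows = np.repeat(np.arange(self.n_samples), w * w)
        mat = sp.coo_matrix(
            (vals.ravel(), (rows, cols.ravel())),
            shape=(self.n_samples, ng * ng),
        )
        return mat.tocsr()

    def _build_deapod(self) -> np.ndarray:
        x = np.arange(self.n) - self.n // 2
        c1 = _kb_fourier(x / self.ng, self.width, self.beta)
        return np.outer(c1, c1)

    def _embed(self, image: np.ndarray) -> np.ndarray:
        """Place a centre-origin image into the unshifted oversampled grid.

        Centre-origin coordinate u (in [-n/2, n/2)) lives at FFT index
        ``u mod ng``; writing the four quadrants directly absorbs the
        ifftshift into the zero-padding.
        """
        b = image.shape[0]
        n2 = self.n // 2
        out = np.zeros((b, self.ng, self.ng), dtype=np.complex128)
        out[:, :n2, :n2] = image[:, n2:, n2:]
        out[:, :n2, -n2:] = image[:, n2:, :n2]
        out[:, -n2:, :n2] = image[:, :n2, n2:]
        out[:, -n2:, -n2:] = image[:, :n2, :n2]
        return out

    def _extract(self, grid: np.ndarray) -> np.ndarray:
        b = grid.shape[0]
        n2 = self.n // 2
        out = np.empty((b, self.n, self.n), dtype=np.complex128)
        out[:, n2:, n2:] = grid[:, :n2, :n2]
        out[:, n2:, :n2] = grid[:, :n2, -n2:]
        out[:, :n2, n2:] = grid[:, -n2:, :n2]
        out[:, :n2, :n2] = grid[:, -n2:, -n2:]
        return out

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.complex128)
        batch = image.shape[:-2]
        flat = image.reshape(-1, self.n, self.n) / self._deapod[None]
        spec = np.fft.fft2(self._embed(flat))
        out = self._interp @ spec.reshape(-1, self.ng * self.ng).T
        return np.ascontiguousarray(out.T).reshape(*batch, self.n_samples)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        samples = np.asarray(samples, dtype=np.complex128)
        batch = samples.shape[:-1]
        flat = samples.reshape(-1, self.n_samples)
        grid = (self._interp.conj().T @ flat.T).T.reshape(-1, self.ng, self.ng)
        img = np.fft.ifft2(grid) * (self.ng * self.ng)
        out = self._extract(img) / self._deapod[None]
        return out.reshape(*batch, self.n, self.n)


def make_plan(
    kx: np.ndarray,
    ky: np.ndarray,
    n: int,
    backend: str = "nufft",
    **kwargs,
):
    """Build a transform plan for one frame's sample coordinates."""
    if backend == "dft":
        return DirectDft2(kx, ky, n)
    if backend == "nufft":
        return KaiserBesselNufft2(kx, ky, n, **kwargs)
    raise ValueError(f"unknown backend {backend!r}")
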