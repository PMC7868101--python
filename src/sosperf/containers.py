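"""Shared in-memory containers for dynamic volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DynamicVolume:
    """Complex 3D+time image stack with voxel geometry and frame timing.

    Attributes
    ----------
    data : ndarray, complex, shape (n_frames, n_slices, ny, nx)
        One volume per cardiac cycle; all slices of a frame share the same
        cardiac phase.
    voxel_size_mm : tuple (dz, dy, dx)
        Voxel edge lengths in mm (through-plane first; 5 mm default slabs).
    frame_times_s : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    provenance : str
        One of ``phantom``, ``gridding``, ``stcr``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (5.0, 2.5, 2.5)
    frame_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("DynamicVolume data must be 4-D (frame, slice, y, x)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DynamicVolume contains non-finite values")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.data.shape[0], dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.data.shape[0],):
            raise ValueError("frame_times_s length must match frame count")
        if self.data.shape[0] > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def copy_with(self, data: np.ndarray, provenance: str | None = None) -> "DynamicVolume":
        return DynamicVolume(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            frame_times_s=self.frame_times_s.copy(),
            provenance=provenance or self.provenance,
        )
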