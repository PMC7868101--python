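"""Stack-of-stars acquisition geometry.

A stack-of-stars (SOS) acquisition samples k-space with radial spokes
in-plane and a Cartesian phase-encode ladder along the slab axis (kz
"partitions").  One image frame is acquired per cardiac cycle ("shot");
within a shot every spoke angle is acquired at every partition.

Conventions used throughout the package:

* in-plane k-space coordinates are normalised to cycles per in-plane
  field of view unit, bounded by ``k_max = 0.5``;
* spoke angles live in ``[0, pi)`` (a radial line through DC covers both
  half-planes);
* the golden-angle increment is ``pi * (sqrt(5) - 1) / 2`` ≈ 1.941611 rad
  ≈ 111.246°, the standard choice for radial MRI because any contiguous
  run of spokes covers the half-circle near-uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Golden-angle spoke increment in radians (≈ 111.246°).
GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SamplingPattern:
    """Full geometric description of a stack-of-stars acquisition.

    Attributes
    ----------
    n_readout : int
        Samples per spoke (even).  With ``readout_oversampling`` 2 this is
        twice the reconstructed in-plane matrix size.
    n_spokes_per_frame : int
        Radial spokes acquired per frame (per cardiac cycle).
    n_frames : int
        Number of dynamic frames.
    n_partitions : int
        Cartesian kz partitions; each reconstructs to one slice.
    angle_schedule : ndarray, shape (n_frames, n_spokes_per_frame)
        Spoke angle in radians, in ``[0, pi)``.
    kz_order : ndarray, shape (n_partitions,)
        Acquisition order of partitions within a shot (a permutation of
        ``0..n_partitions-1``); centric by default so the k-space centre
        is acquired first, timed to the end-systolic pause.
    k_max : float
        Normalised in-plane spatial-frequency bound (0.5).
    readout_oversampling : float
        Readout oversampling ratio (>= 1).
    tr_ms : float
        Repetition time of one k-space line, in milliseconds.
    """

    n_readout: int = 128
    n_spokes_per_frame: int = 5
    n_frames: int = 40
    n_partitions: int = 16
    angle_schedule: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    kz_order: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    k_max: float = 0.5
    readout_oversampling: float = 2.0
    tr_ms: float = 2.35

    def __post_init__(self) -> None:
        if self.n_readout < 2 or self.n_readout % 2 != 0:
            raise ValueError(f"n_readout must be a positive even integer, got {self.n_readout}")
        for name in ("n_spokes_per_frame", "n_frames", "n_partitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.readout_oversampling < 1.0:
            raise ValueError("readout_oversampling must be >= 1")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.angle_schedule is None:
            object.__setattr__(
                self,
                "angle_schedule",
                golden_angle_schedule(self.n_frames, self.n_spokes_per_frame),
            )
        angles = np.asarray(self.angle_schedule, dtype=float)
        if angles.shape != (self.n_frames, self.n_spokes_per_frame):
            raise ValueError(
                f"angle_schedule shape {angles.shape} inconsistent with "
                f"({self.n_frames}, {self.n_spokes_per_frame})"
            )
        if np.any(angles < 0.0) or np.any(angles >= np.pi):
            raise ValueError("all angles must lie in [0, pi)")
        for f in range(self.n_frames):
            if len(np.unique(angles[f])) != self.n_spokes_per_frame:
                raise ValueError(f"angles within frame {f} are not distinct")
        object.__setattr__(self, "angle_schedule", angles)
        if self.kz_order is None:
            object.__setattr__(self, "kz_order", centric_order(self.n_partitions))
        kz = np.asarray(self.kz_order, dtype=int)
        if sorted(kz.tolist()) != list(range(self.n_partitions)):
            raise ValueError("kz_order must be a permutation of 0..n_partitions-1")
        object.__setattr__(self, "kz_order", kz)

    # -- derived geometry -------------------------------------------------

    @property
    def grid_size(self) -> int:
        """Reconstructed in-plane matrix size implied by the readout."""
        return int(round(self.n_readout / self.readout_oversampling))

    def readout_radii(self) -> np.ndarray:
        """Signed normalised radial coordinate of each readout sample.

        Samples span ``[-k_max, k_max)`` with spacing ``2*k_max/n_readout``;
        the DC sample sits at readout index ``n_readout // 2``.
        """
        idx = np.arange(self.n_readout) - self.n_readout // 2
        return idx * (2.0 * self.k_max / self.n_readout)

    def spoke_coordinates(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky) arrays of shape (n_spokes_per_frame, n_readout) for one frame."""
        r = self.readout_radii()
        ang = self.angle_schedule[frame][:, None]
        return r[None, :] * np.cos(ang), r[None, :] * np.sin(ang)

    @property
    def lines_per_shot(self) -> int:
        """k-space lines acquired within one cardiac cycle."""
        return self.n_spokes_per_frame * self.n_partitions


def golden_angle_schedule(
    n_frames: int, n_spokes_per_frame: int, mode: str = "continuous"
) -> np.ndarray:
    """Spoke-angle schedule over a dynamic series.

    Parameters
    ----------
    n_frames, n_spokes_per_frame : int
        Series dimensions, both >= 1.
    mode : {"continuous", "per_frame"}
        ``continuous`` advances the golden-angle sequence across the whole
        series (spoke ``k`` globally has angle ``k * GOLDEN_ANGLE mod pi``),
        so retrospectively binned subsets stay near-uniform; ``per_frame``
        restarts the sequence at every frame.

    Returns
    -------
    ndarray of shape (n_frames, n_spokes_per_frame), angles in [0, pi).
    """
    if n_frames < 1 or n_spokes_per_frame < 1:
        raise ValueError("n_frames and n_spokes_per_frame must be >= 1")
    if mode not in ("continuous", "per_frame"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "continuous":
        k = np.arange(n_frames * n_spokes_per_frame)
        angles = np.mod(k * GOLDEN_ANGLE, np.pi)
        return angles.reshape(n_frames, n_spokes_per_frame)
    k = np.arange(n_spokes_per_frame)
    row = np.mod(k * GOLDEN_ANGLE, np.pi)
    return np.tile(row, (n_frames, 1))


def centric_order(n_partitions: int) -> np.ndarray:
    """Centric kz ordering: centre partition first, then alternating out.

    The centre of k-space is acquired first so that the contrast-defining
    data fall in the end-systolic pause.  Ties between the two sides are
    broken towards the lower partition index.
    """
    centre = n_partitions // 2
    order = [centre]
    for step in range(1, n_partitions):
        for sign in (-1, 1):
            p = centre + sign * step
            if 0 <= p < n_partitions and p not in order:
                order.append(p)
    return np.asarray(order[:n_partitions], dtype=int)


def build_pattern(config: dict | None = None, **overrides) -> SamplingPattern:
    """Build a :class:`SamplingPattern` from a config mapping plus overrides.

    The default configuration is the package's reference stack: 16 kz
    partitions (12 interior slices remain after the 4-slice edge discard),
    continuous golden-angle ordering, centric kz, readout oversampling 2,
    and a per-shot line budget whose duration accounting yields 188 ms.
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    mode = cfg.pop("angle_mode", "continuous")
    known = {
        "n_readout", "n_spokes_per_frame", "n_frames", "n_partitions",
        "angle_schedule", "kz_order", "k_max", "readout_oversampling", "tr_ms",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown SamplingPattern fields: {sorted(unknown)}")
    if "angle_schedule" not in cfg:
        n_frames = int(cfg.get("n_frames", 40))
        n_spokes = int(cfg.get("n_spokes_per_frame", 5))
        cfg["angle_schedule"] = golden_angle_schedule(n_frames, n_spokes, mode)
        cfg["n_frames"] = n_frames
        cfg["n_spokes_per_frame"] = n_spokes
    return SamplingPattern(**cfg)


def density_compensation(pattern: SamplingPattern) -> np.ndarray:
    """Ramp density-compensation weights, shape (n_spokes_per_frame, n_readout).

    Off-centre samples get weight proportional to ``|k|`` (the Jacobian of
    polar sampling); the DC sample gets the continuum limit of the ramp
    integrated over the central cell, ``dk / 8`` per spoke, so the total
    weight is a Riemann sum of the sampled k-space disc.  Weights are
    normalised so that summed over one frame's spokes, readout points and
    all partitions they equal ``pi * k_max**2 * n_partitions``.

    The weights do not depend on the frame (|k| is the same for every
    golden-angle spoke), so one (spoke, readout) array serves all frames;
    broadcast over partitions when applying.
    """
    r = np.abs(pattern.readout_radii())
    dk = 2.0 * pattern.k_max / pattern.n_readout
    w = r.copy()
    w[pattern.n_readout // 2] = dk / 8.0
    w = np.tile(w, (pattern.n_spokes_per_frame, 1))
    target = np.pi * pattern.k_max**2
    w *= target / w.sum()
    return w


def shot_duration(pattern: SamplingPattern, tr_ms: float | None = None) -> float:
    """Duration in ms of one shot: ``tr_ms * lines acquired per cardiac cycle``.

    The default pattern (TR 2.35 ms, 5 spokes/frame, 16 partitions) yields
    a 188 ms shot.
    """
    tr = pattern.tr_ms if tr_ms is None else float(tr_ms)
    if tr <= 0:
        raise ValueError("tr_ms must be positive")
    return tr * pattern.lines_per_shot
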