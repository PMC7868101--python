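"""Dynamic first-pass perfusion phantom.

Generates ground-truth 3D+time volumes that emulate the first pass of a
gadolinium bolus through the left ventricle under free breathing:

* a gamma-variate arterial input function (AIF) stands in for the
  power-injected bolus concentration in the LV blood pool;
* a one-compartment tracer-kinetic model (Ktrans / kep) drives myocardial
  enhancement, with wedge-shaped hypoperfused regions of configurable
  angular extent, slice range, transmural depth and flow reduction;
* a saturation-recovery signal equation converts concentration to
  T1-weighted image intensity;
* respiratory motion is a rigid sinusoidal translation, one position per
  cardiac cycle, applied by re-rendering the analytic geometry (no
  resampling blur);
* ECG mis-triggering randomly perturbs frame geometry, mimicking frames
  acquired at the wrong cardiac phase.

The anatomy is an ellipsoidal LV shell: per slice the myocardium is an
annulus whose endo/epi radii follow elliptical profiles along the long
(slab) axis.  Transient dark artefacts are *not* injected explicitly;
they emerge downstream from angular undersampling of the sharp
bloodpool/myocardium contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DynamicVolume

LABEL_BACKGROUND = 0
LABEL_BLOODPOOL = 1
LABEL_MYOCARDIUM = 2
LABEL_DEFECT_BASE = 3  # defect k has label LABEL_DEFECT_BASE + k


@dataclass
class AIFParams:
    """Gamma-variate arterial input: peak amplitude A (mM), bolus arrival
    t0 (s), shape alpha (unitless), scale beta (s)."""

    A: float = 5.0
    t0: float = 3.0
    alpha: float = 2.5
    beta: float = 1.5


@dataclass
class TissueParams:
    """One-compartment kinetics + relaxometry for one tissue class.

    Ktrans, kep in 1/s; R1_0 baseline longitudinal rate (1/s); r1 contrast
    relaxivity (1/(mM*s)); M0 equilibrium signal (arbitrary units).
    Defaults are stress-level myocardium at 3 T.
    """

    Ktrans: float = 0.025
    kep: float = 0.10
    R1_0: float = 0.83
    r1: float = 4.5
    M0: float = 1.0


@dataclass
class LVGeometry:
    """Ellipsoidal-shell left ventricle, dimensions in mm."""

    endo_radius: float = 15.0
    epi_radius: float = 25.0
    long_axis_extent: float = 70.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x) offset


@dataclass
class DefectSpec:
    """Wedge-shaped hypoperfusion: angular span (deg, anatomical angle),
    inclusive partition span, transmural fraction from the endocardium,
    and fractional flow reduction."""

    angle_start_deg: float = 120.0
    angle_span_deg: float = 70.0
    partition_lo: int = 4
    partition_hi: int = 8
    transmural_fraction: float = 1.0
    flow_reduction: float = 0.8


@dataclass
class MotionSpec:
    """Rigid sinusoidal respiratory translation; amplitude per (z, y, x) axis."""

    amplitude_mm: tuple[float, float, float] = (3.0, 2.0, 0.0)
    period_s: float = 4.2


@dataclass
class TriggerSpec:
    """Cardiac triggering: RR interval, trigger jitter, mis-trigger model."""

    rr_s: float = 0.8
    jitter_sd_s: float = 0.010
    mistrigger_prob: float = 0.0
    mistrigger_shift_mm: float = 6.0


@dataclass
class PhantomSpec:
    """Full generative description of one simulated first-pass scan."""

    nx: int = 64
    ny: int = 64
    nz: int = 16
    voxel_mm: tuple[float, float, float] = (2.5, 2.5, 5.0)  # (dx, dy, dz)
    lv: LVGeometry = field(default_factory=LVGeometry)
    aif: AIFParams = field(default_factory=AIFParams)
    blood: TissueParams = field(
        default_factory=lambda: TissueParams(Ktrans=0.0, kep=0.0, R1_0=0.62)
    )
    myocardium: TissueParams = field(default_factory=TissueParams)
    defects: list[DefectSpec] = field(default_factory=list)
    motion: MotionSpec = field(default_factory=MotionSpec)
    trigger: TriggerSpec = field(default_factory=TriggerSpec)
    n_frames: int = 40
    ts_s: float = 0.10  # saturation-recovery delay
    background_signal: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.lv.endo_radius >= self.lv.epi_radius:
            raise ValueError("endocardial radius must be < epicardial radius")
        for t in (self.blood, self.myocardium):
            if t.Ktrans < 0 or t.kep < 0 or t.R1_0 < 0 or t.r1 < 0:
                raise ValueError("rate constants must be nonnegative")
        for d in self.defects:
            if not (0.0 < d.transmural_fraction <= 1.0):
                raise ValueError("transmural_fraction must be in (0, 1]")
            if not (0.0 <= d.flow_reduction < 1.0):
                raise ValueError("flow_reduction must be in [0, 1)")
            if not (0 <= d.partition_lo <= d.partition_hi < self.nz):
                raise ValueError(
                    f"defect partition span [{d.partition_lo}, {d.partition_hi}] "
                    f"exceeds geometry (nz={self.nz})"
                )
            if not (0.0 < d.angle_span_deg <= 360.0):
                raise ValueError("angle_span_deg must be in (0, 360]")


@dataclass
class GroundTruth:
    """Companion truth for a rendered phantom."""

    labels: np.ndarray  # int8 (frame, nz, ny, nx)
    shifts_mm: np.ndarray  # (frame, 3) rigid (z, y, x) translation
    trigger_offsets_s: np.ndarray  # (frame,)
    mistrigger_flags: np.ndarray  # bool (frame,)
    curves_mM: dict[str, np.ndarray]  # per-region concentration at frame times
    signals: dict[str, np.ndarray]  # per-region signal intensity at frame times
    frame_times_s: np.ndarray
    voxel_mm: tuple[float, float, float]  # (dx, dy, dz)
    lv: LVGeometry = field(default_factory=LVGeometry)

    def region_mask(self, label: int, frame: int = 0) -> np.ndarray:
        return self.labels[frame] == label

    def myocardial_mask(self, frame: int = 0) -> np.ndarray:
        return self.labels[frame] >= LABEL_MYOCARDIUM


def aif_curve(
    times: np.ndarray, A: float, t0: float, alpha: float, beta: float
) -> np.ndarray:
    """Peak-normalised gamma-variate bolus: c(t) = A ((t-t0)/(alpha*beta))^alpha
    * exp(alpha - (t-t0)/beta) for t > t0, else 0; peak value A at t0 + alpha*beta."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    tau = t - t0
    pos = tau > 0
    out[pos] = A * (tau[pos] / (alpha * beta)) ** alpha * np.exp(alpha - tau[pos] / beta)
    return out


def tissue_concentration(
    aif: np.ndarray, Ktrans: float, kep: float, dt: float
) -> np.ndarray:
    """One-compartment tissue uptake by trapezoidal convolution:

    C(t) = Ktrans * int_0^t aif(tau) exp(-kep (t - tau)) dtau.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if Ktrans < 0 or kep < 0:
        raise ValueError("Ktrans and kep must be nonnegative")
    a = np.asarray(aif, dtype=float)
    n = a.size
    t = np.arange(n) * dt
    h = np.exp(-kep * t)
    conv = np.convolve(a, h)[:n]
    trap = conv - 0.5 * (a[0] * h + a * h[0])
    return Ktrans * dt * trap


def signal_from_concentration(
    C: np.ndarray | float, M0: float, R1_0: float, r1: float, TS: float
) -> np.ndarray:
    """Saturation-recovery T1-weighted signal S = M0 (1 - exp(-TS (R1_0 + r1 C)));
    monotone increasing in concentration."""
    if TS <= 0:
        raise ValueError("TS must be positive")
    C = np.asarray(C, dtype=float)
    return M0 * (1.0 - np.exp(-TS * (R1_0 + r1 * C)))


def simulate_triggers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame trigger offsets (s) and mis-trigger flags.

    Normal frames get offset ~ N(0, jitter_sd); with probability
    ``mistrigger_prob`` a frame is flagged and its offset drawn uniformly
    from +/- RR/2 (a failed R-wave detection lands anywhere in the cycle).
    Reproducible under the spec seed.
    """
    tg = spec.trigger
    if not (0.0 <= tg.mistrigger_prob <= 1.0):
        raise ValueError("mistrigger_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7269]))
    offsets = rng.normal(0.0, tg.jitter_sd_s, spec.n_frames) if tg.jitter_sd_s > 0 else np.zeros(spec.n_frames)
    flags = rng.random(spec.n_frames) < tg.mistrigger_prob
    if flags.any():
        offsets[flags] = rng.uniform(-tg.rr_s / 2.0, tg.rr_s / 2.0, int(flags.sum()))
    return offsets, flags


def _region_curves(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Concentration and signal curves per region, sampled at frame times."""
    frame_times = np.arange(spec.n_frames) * spec.trigger.rr_s
    dt = 0.02
    t_fine = np.arange(0.0, frame_times[-1] + spec.trigger.rr_s + dt, dt)
    aif_fine = aif_curve(t_fine, spec.aif.A, spec.aif.t0, spec.aif.alpha, spec.aif.beta)

    curves: dict[str, np.ndarray] = {}
    signals: dict[str, np.ndarray] = {}

    curves["bloodpool"] = np.interp(frame_times, t_fine, aif_fine)
    b = spec.blood
    signals["bloodpool"] = signal_from_concentration(
        curves["bloodpool"], b.M0, b.R1_0, b.r1, spec.ts_s
    )

    m = spec.myocardium
    myo_fine = tissue_concentration(aif_fine, m.Ktrans, m.kep, dt)
    curves["myocardium"] = np.interp(frame_times, t_fine, myo_fine)
    signals["myocardium"] = signal_from_concentration(
        curves["myocardium"], m.M0, m.R1_0, m.r1, spec.ts_s
    )

    for k, d in enumerate(spec.defects):
        fine = tissue_concentration(aif_fine, m.Ktrans * (1.0 - d.flow_reduction), m.kep, dt)
        name = f"defect-{k}"
        curves[name] = np.interp(frame_times, t_fine, fine)
        signals[name] = signal_from_concentration(
            curves[name], m.M0, m.R1_0, m.r1, spec.ts_s
        )
    return curves, signals, frame_times


def _slice_radii(z_lv: float, lv: LVGeometry) -> tuple[float, float]:
    """Endo/epi annulus radii of the ellipsoidal shell at long-axis offset z_lv."""
    c_epi = lv.long_axis_extent / 2.0
    c_endo = c_epi * lv.endo_radius / lv.epi_radius
    u_epi = 1.0 - (z_lv / c_epi) ** 2
    u_endo = 1.0 - (z_lv / c_endo) ** 2
    r_epi = lv.epi_radius * np.sqrt(u_epi) if u_epi > 0 else 0.0
    r_endo = lv.endo_radius * np.sqrt(u_endo) if u_endo > 0 else 0.0
    return r_endo, r_epi


def anatomical_angle_deg(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    """Anatomical circumferential angle in degrees, [0, 360).

    0 deg = anterior (-y in array coordinates, i.e. image "up"), increasing
    clockwise on the displayed short-axis image through septum (90 deg),
    inferior (180 deg) and lateral wall (270 deg).
    """
    return np.mod(np.degrees(np.arctan2(-dx, -dy)), 360.0)


def render_dynamic_phantom(spec: PhantomSpec) -> tuple[DynamicVolume, GroundTruth]:
    """Rasterise the dynamic phantom and its ground truth.

    Geometry is re-rendered analytically each frame under the rigid
    respiratory shift (plus an extra in-plane shift on mis-triggered
    frames), so no interpolation blur enters the images.
    """
    curves, signals, frame_times = _region_curves(spec)
    offsets, flags = simulate_triggers(spec)
    dx, dy, dz = spec.voxel_mm
    nz, ny, nx = spec.nz, spec.ny, spec.nx

    # voxel-centre coordinates relative to the grid centre (DC convention)
    xs = (np.arange(nx) - nx // 2) * dx
    ys = (np.arange(ny) - ny // 2) * dy
    zs = (np.arange(nz) - nz // 2) * dz
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    cz0, cy0, cx0 = spec.lv.center_mm

    # tissue-fixed defect extents (LV frame)
    defect_z = [
        ((d.partition_lo - nz // 2 - 0.5) * dz, (d.partition_hi - nz // 2 + 0.5) * dz)
        for d in spec.defects
    ]

    amp = np.asarray(spec.motion.amplitude_mm, dtype=float)
    shifts = amp[None, :] * np.sin(
        2.0 * np.pi * frame_times[:, None] / spec.motion.period_s
    )
    # mis-triggered frames: wrong cardiac phase -> extra in-plane displacement
    extra = np.zeros_like(shifts)
    extra[flags, 1] = (
        spec.trigger.mistrigger_shift_mm * offsets[flags] / (spec.trigger.rr_s / 2.0)
    )
    shifts = shifts + extra

    labels = np.zeros((spec.n_frames, nz, ny, nx), dtype=np.int8)
    vol = np.full(
        (spec.n_frames, nz, ny, nx), spec.background_signal, dtype=np.complex128
    )

    for f in range(spec.n_frames):
        sz, sy, sx = shifts[f]
        cy = cy0 + sy
        cx = cx0 + sx
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ang = anatomical_angle_deg(yy - cy, xx - cx)
        for p in range(nz):
            z_lv = zs[p] - cz0 - sz
            r_endo, r_epi = _slice_radii(z_lv, spec.lv)
            if r_epi <= 0:
                continue
            blood = rho < r_endo
            myo = (rho >= r_endo) & (rho < r_epi)
            labels[f, p][blood] = LABEL_BLOODPOOL
            labels[f, p][myo] = LABEL_MYOCARDIUM
            vol[f, p][blood] = signals["bloodpool"][f]
            vol[f, p][myo] = signals["myocardium"][f]
            if r_epi > r_endo:
                tau = np.clip((rho - r_endo) / (r_epi - r_endo), 0.0, 1.0)
            else:
                tau = np.zeros_like(rho)
            for k, d in enumerate(spec.defects):
                z_lo, z_hi = defect_z[k]
                if not (z_lo <= z_lv <= z_hi):
                    continue
                in_angle = np.mod(ang - d.angle_start_deg, 360.0) < d.angle_span_deg
                wedge = myo & in_angle & (tau < d.transmural_fraction)
                labels[f, p][wedge] = LABEL_DEFECT_BASE + k
                vol[f, p][wedge] = signals[f"defect-{k}"][f]

    volume = DynamicVolume(
        data=vol,
        voxel_size_mm=(dz, dy, dx),
        frame_times_s=frame_times,
        provenance="phantom",
    )
    gt = GroundTruth(
        labels=labels,
        shifts_mm=shifts,
        trigger_offsets_s=offsets,
        mistrigger_flags=flags,
        curves_mM=curves,
        signals=signals,
        frame_times_s=frame_times,
        voxel_mm=spec.voxel_mm,
        lv=spec.lv,
    )
    return volume, gt
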