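"""Regional reading of reconstructed first-pass series.

Mirrors how dynamic perfusion series are read clinically: slice-stack
edge discard, 16-segment AHA division of the LV myocardium, segment
intensity-time curves against a remote reference, discrimination of
transient dark artefacts (short dips around the bloodpool contrast peak,
the dark-rim-artefact signature) from persistent perfusion defects, and
a composite severity grade combining depth of intensity deficit,
transmurality and temporal persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import DynamicVolume
from .phantom import (
    LABEL_DEFECT_BASE,
    GroundTruth,
    LVGeometry,
    _slice_radii,
    anatomical_angle_deg,
)

logger = logging.getLogger(__name__)

#: AHA 16-segment names: 6 basal, 6 mid, 4 apical.
AHA_SEGMENT_NAMES = (
    "basal anterior", "basal anteroseptal", "basal inferoseptal",
    "basal inferior", "basal inferolateral", "basal anterolateral",
    "mid anterior", "mid anteroseptal", "mid inferoseptal",
    "mid inferior", "mid inferolateral", "mid anterolateral",
    "apical anterior", "apical septal", "apical inferior", "apical lateral",
)

# sector start angles (deg, anatomical: 0 = anterior, clockwise via septum)
_SECTOR6_START = -30.0
_SECTOR4_START = -45.0


@dataclass
class LVModel:
    """Analytic LV geometry for segmentation, usually from phantom truth.

    ``centers_mm`` holds the per-frame (z, y, x) LV centre relative to the
    grid centre; ``slice_offset`` accounts for discarded edge slices.
    """

    lv: LVGeometry
    voxel_mm: tuple[float, float, float]  # (dx, dy, dz)
    centers_mm: np.ndarray  # (n_frames, 3)
    slice_offset: int = 0

    @classmethod
    def from_ground_truth(cls, gt: GroundTruth) -> "LVModel":
        base = np.asarray(gt.lv.center_mm, dtype=float)
        return cls(
            lv=gt.lv,
            voxel_mm=gt.voxel_mm,
            centers_mm=base[None, :] + gt.shifts_mm,
        )

    def with_slice_offset(self, offset: int) -> "LVModel":
        return LVModel(self.lv, self.voxel_mm, self.centers_mm, slice_offset=offset)


@dataclass
class SegmentTimeCurves:
    """Per-frame mean magnitude for the 16 AHA segments plus references."""

    curves: np.ndarray  # (16, n_frames)
    endo_curves: np.ndarray  # (16, n_frames) subendocardial halves
    epi_curves: np.ndarray  # (16, n_frames) subepicardial halves
    bloodpool: np.ndarray  # (n_frames,)
    frame_times_s: np.ndarray
    coverage: np.ndarray | None = None  # (16, n_frames) voxel counts
    segment_names: tuple[str, ...] = AHA_SEGMENT_NAMES
    remote: np.ndarray | None = None
    remote_is_fallback: bool = False

    @property
    def n_frames(self) -> int:
        return self.curves.shape[1]


@dataclass
class DefectFinding:
    """One flagged hypointense run in one AHA segment."""

    segment_id: int
    segment_name: str
    onset_frame: int
    persistence: int  # consecutive frames below threshold
    depth: float  # peak relative deficit vs remote, in [0, 1]
    transmurality: float  # in [0, 1]
    classification: str  # "transient-artifact" | "persistent-defect"
    severity: str = "none"  # none | mild | moderate | severe

    def __post_init__(self) -> None:
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


def discard_edge_slices(volume: DynamicVolume, n_edge: int = 4) -> DynamicVolume:
    """Drop ``n_edge/2`` slices from each slab end (slab-excitation edges).

    The default policy keeps 12 of 16 five-mm slices, the displayed stack.
    """
    if n_edge % 2 != 0 or n_edge < 0:
        raise ValueError("n_edge must be a nonnegative even integer")
    if n_edge >= volume.n_slices:
        raise ValueError(
            f"cannot discard {n_edge} of {volume.n_slices} slices"
        )
    if n_edge == 0:
        return volume
    half = n_edge // 2
    return volume.copy_with(volume.data[:, half:-half])


def _segment_id(z_lv: float, ang_deg: np.ndarray, band_edges: tuple[float, float]) -> np.ndarray:
    """Map angles to the AHA segment id for the band containing z_lv."""
    z_basal, z_apical = band_edges
    if z_lv <= z_basal:
        base_id, n_sect, start = 0, 6, _SECTOR6_START
    elif z_lv <= z_apical:
        base_id, n_sect, start = 6, 6, _SECTOR6_START
    else:
        base_id, n_sect, start = 12, 4, _SECTOR4_START
    sect = np.floor(np.mod(ang_deg - start, 360.0) / (360.0 / n_sect)).astype(int)
    return base_id + np.clip(sect, 0, n_sect - 1)


def aha_segment_curves(volume: DynamicVolume, lv_model: LVModel) -> SegmentTimeCurves:
    """Assign myocardial voxels to 16 AHA segments and average per frame.

    Slices are banded basal/mid/apical by thirds of the LV long-axis
    extent (base at low slice index); basal and mid bands use six 60-deg
    sectors, the apical band four 90-deg sectors.  Each segment is also
    split at mid-wall into subendocardial and subepicardial halves for
    transmurality estimation.
    """
    mag = volume.magnitude
    n_frames, nz, ny, nx = mag.shape
    dx, dy, dz = lv_model.voxel_mm
    half_L = lv_model.lv.long_axis_extent / 2.0
    # band edges along the LV long axis: base (negative z) -> apex
    z_basal = -half_L + 2.0 * half_L / 3.0
    z_apical = -half_L + 4.0 * half_L / 3.0

    xs = (np.arange(nx) - nx // 2) * dx
    ys = (np.arange(ny) - ny // 2) * dy
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    total = np.zeros((16, n_frames))
    count = np.zeros((16, n_frames))
    total_endo = np.zeros((16, n_frames))
    count_endo = np.zeros((16, n_frames))
    total_epi = np.zeros((16, n_frames))
    count_epi = np.zeros((16, n_frames))
    blood_total = np.zeros(n_frames)
    blood_count = np.zeros(n_frames)

    nz_full = nz + 2 * lv_model.slice_offset
    for f in range(n_frames):
        cz, cy, cx = lv_model.centers_mm[min(f, len(lv_model.centers_mm) - 1)]
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ang = anatomical_angle_deg(yy - cy, xx - cx)
        for p in range(nz):
            z_mm = (p + lv_model.slice_offset - nz_full // 2) * dz
            z_lv = z_mm - cz
            r_endo, r_epi = _slice_radii(z_lv, lv_model.lv)
            if r_epi <= 0:
                continue
            myo = (rho >= r_endo) & (rho < r_epi)
            blood = rho < r_endo
            blood_total[f] += mag[f, p][blood].sum()
            blood_count[f] += blood.sum()
            if not myo.any():
                continue
            seg = _segment_id(z_lv, ang, (z_basal, z_apical))
            tau = (rho - r_endo) / max(r_epi - r_endo, 1e-9)
            endo = myo & (tau < 0.5)
            epi = myo & (tau >= 0.5)
            vals = mag[f, p]
            np.add.at(total[:, f], seg[myo], vals[myo])
            np.add.at(count[:, f], seg[myo], 1)
            np.add.at(total_endo[:, f], seg[endo], vals[endo])
            np.add.at(count_endo[:, f], seg[endo], 1)
            np.add.at(total_epi[:, f], seg[epi], vals[epi])
            np.add.at(count_epi[:, f], seg[epi], 1)

    if count.sum() == 0:
        raise ValueError("empty myocardial mask")
    # a segment may lack voxels in some frames (apex drifting out of the
    # retained slices under respiratory z-shift); its coverage array lets
    # the classifier ignore those frames instead of reading zero intensity
    curves = total / np.maximum(count, 1)
    endo_curves = total_endo / np.maximum(count_endo, 1)
    epi_curves = total_epi / np.maximum(count_epi, 1)
    bloodpool = blood_total / np.maximum(blood_count, 1)
    return SegmentTimeCurves(
        curves=curves,
        endo_curves=endo_curves,
        epi_curves=epi_curves,
        bloodpool=bloodpool,
        frame_times_s=volume.frame_times_s.copy(),
        coverage=count,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True in a 1-D boolean array."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def classify_hypointensity(
    curves: SegmentTimeCurves,
    threshold_frac: float = 0.15,
    persist_min: int = 5,
    artifact_window: int = 3,
    grade: bool = True,
    pass_length_frames: int | None = None,
) -> list[DefectFinding]:
    """Flag hypointense segment runs and classify artefact vs defect.

    A segment is "below" at frame t when its mean intensity drops under
    ``remote(t) * (1 - threshold_frac)``.  The remote reference is the
    mean of segments that never dip below threshold (median of all
    segments when every segment dips — logged as a global-artifact
    fallback).  Runs lasting >= ``persist_min`` frames that extend beyond
    the bloodpool-peak window (+/- ``artifact_window`` frames around the
    bloodpool maximum, where dark-rim-type artefacts live) are persistent
    defects; every other run is a transient artefact.  Detection starts
    at bolus arrival (bloodpool above 20% of peak).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must be in (0, 1)")
    if persist_min < 1:
        raise ValueError("persist_min must be >= 1")
    n_seg, n_frames = curves.curves.shape

    peak = int(np.argmax(curves.bloodpool))
    arrival = int(np.argmax(curves.bloodpool >= 0.2 * curves.bloodpool[peak]))
    active = np.zeros(n_frames, dtype=bool)
    active[arrival:] = True

    covered = (
        curves.coverage > 0
        if curves.coverage is not None
        else np.ones((n_seg, n_frames), dtype=bool)
    )
    masked = np.ma.MaskedArray(curves.curves, mask=~covered)
    provisional = np.ma.median(masked, axis=0).filled(0.0)
    below_prov = curves.curves < (1.0 - threshold_frac) * provisional[None, :]
    below_prov &= active[None, :] & covered
    never_below = ~below_prov.any(axis=1)
    if never_below.any():
        rem = np.ma.mean(masked[never_below], axis=0)
        remote = np.where(np.ma.getmaskarray(rem), provisional, rem.filled(0.0))
        fallback = False
    else:
        remote = provisional
        fallback = True
        logger.warning(
            "all 16 segments dip below threshold; using median-segment remote "
            "(global-artifact fallback)"
        )
    curves.remote = remote
    curves.remote_is_fallback = fallback

    safe_remote = np.maximum(remote, 1e-12)
    below = curves.curves < (1.0 - threshold_frac) * remote[None, :]
    below &= active[None, :] & covered

    window_lo, window_hi = peak - artifact_window, peak + artifact_window
    if pass_length_frames is None:
        pass_length_frames = max(n_frames - peak, 1)

    findings: list[DefectFinding] = []
    for s in range(n_seg):
        for start, length in _runs(below[s]):
            end = start + length - 1
            frames = slice(start, end + 1)
            deficit = (remote[frames] - curves.curves[s, frames]) / safe_remote[frames]
            depth = float(np.clip(deficit.max(), 0.0, 1.0))
            d_endo = float(
                np.clip(
                    np.mean(
                        (remote[frames] - curves.endo_curves[s, frames])
                        / safe_remote[frames]
                    ),
                    0.0,
                    1.0,
                )
            )
            d_epi = float(
                np.clip(
                    np.mean(
                        (remote[frames] - curves.epi_curves[s, frames])
                        / safe_remote[frames]
                    ),
                    0.0,
                    1.0,
                )
            )
            dmax = max(d_endo, d_epi)
            trans = (d_endo + d_epi) / (2.0 * dmax) if dmax > 1e-9 else 0.5
            extends_beyond = start < window_lo or end > window_hi
            if length >= persist_min and extends_beyond:
                cls = "persistent-defect"
            else:
                cls = "transient-artifact"
            finding = DefectFinding(
                segment_id=s,
                segment_name=AHA_SEGMENT_NAMES[s],
                onset_frame=start,
                persistence=length,
                depth=depth,
                transmurality=float(trans),
                classification=cls,
            )
            if grade and cls == "persistent-defect":
                finding.severity = grade_severity(finding, pass_length_frames)
            findings.append(finding)
    return findings


def grade_severity(
    finding: DefectFinding,
    pass_length_frames: int,
    thresholds: dict[str, float] | None = None,
) -> str:
    """Composite severity from depth x transmurality x normalised persistence.

    s = depth * transmurality * min(1, persistence / pass_length_frames);
    severe >= 0.5, moderate >= 0.2, mild >= 0.05 by default (declared
    conventions for an automatic reading, exposed in config).
    """
    if finding.classification != "persistent-defect":
        raise ValueError("only persistent-defect findings are graded")
    th = thresholds or {"severe": 0.5, "moderate": 0.2, "mild": 0.05}
    s = finding.depth * finding.transmurality * min(
        1.0, finding.persistence / max(pass_length_frames, 1)
    )
    if s >= th["severe"]:
        return "severe"
    if s >= th["moderate"]:
        return "moderate"
    if s >= th["mild"]:
        return "mild"
    return "none"


def true_defect_segments(
    gt: GroundTruth,
    lv_model: LVModel | None = None,
    min_overlap: float = 0.05,
) -> dict[int, int]:
    """Map AHA segment id -> defect index for segments whose myocardial
    voxels overlap an inserted defect by at least ``min_overlap`` (at the
    first frame; analytic geometry, so frames agree up to boundary voxels)."""
    lv_model = lv_model or LVModel.from_ground_truth(gt)
    labels = gt.labels[0]
    nz, ny, nx = labels.shape
    dx, dy, dz = lv_model.voxel_mm
    xs = (np.arange(nx) - nx // 2) * dx
    ys = (np.arange(ny) - ny // 2) * dy
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    cz, cy, cx = lv_model.centers_mm[0]
    half_L = lv_model.lv.long_axis_extent / 2.0
    z_basal = -half_L + 2.0 * half_L / 3.0
    z_apical = -half_L + 4.0 * half_L / 3.0

    seg_total = np.zeros(16)
    seg_defect: dict[int, dict[int, int]] = {}
    for p in range(nz):
        z_lv = (p - nz // 2) * dz - cz
        r_endo, r_epi = _slice_radii(z_lv, lv_model.lv)
        if r_epi <= 0:
            continue
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        myo = (rho >= r_endo) & (rho < r_epi)
        if not myo.any():
            continue
        ang = anatomical_angle_deg(yy - cy, xx - cx)
        seg = _segment_id(z_lv, ang, (z_basal, z_apical))
        lab = labels[p]
        for s in range(16):
            m = myo & (seg == s)
            seg_total[s] += m.sum()
            for k in np.unique(lab[m]):
                if k >= LABEL_DEFECT_BASE:
                    seg_defect.setdefault(s, {}).setdefault(int(k), 0)
                    seg_defect[s][int(k)] += int(np.sum(m & (lab == k)))
    out: dict[int, int] = {}
    for s, counts in seg_defect.items():
        k_best = max(counts, key=counts.get)
        if seg_total[s] > 0 and counts[k_best] / seg_total[s] >= min_overlap:
            out[s] = k_best - LABEL_DEFECT_BASE
    return out


def recovery_metrics(
    findings: list[DefectFinding],
    truth: dict[int, str],
    n_segments: int = 16,
) -> dict[str, float | dict[str, float]]:
    """Segment-level confusion metrics against phantom ground truth.

    ``truth`` maps segment id -> true severity (mild/moderate/severe).
    Returns per-severity sensitivity, specificity over non-defect
    segments, and the Dice overlap of flagged vs true defect segments.
    """
    flagged = {f.segment_id for f in findings if f.classification == "persistent-defect"}
    true_set = set(truth)
    sens: dict[str, float] = {}
    for sev in ("mild", "moderate", "severe"):
        segs = [s for s, v in truth.items() if v == sev]
        if segs:
            sens[sev] = sum(1 for s in segs if s in flagged) / len(segs)
    negatives = n_segments - len(true_set)
    fp = len(flagged - true_set)
    specificity = (negatives - fp) / negatives if negatives > 0 else 1.0
    inter = len(flagged & true_set)
    denom = len(flagged) + len(true_set)
    dice = 2.0 * inter / denom if denom > 0 else 1.0
    return {
        "sensitivity": sens,
        "specificity": specificity,
        "dice": dice,
        "n_flagged": float(len(flagged)),
        "n_true": float(len(true_set)),
        "false_positives": float(fp),
    }
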