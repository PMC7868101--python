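"""File formats and run configuration.

Formats produced and consumed by the toolkit:

* raw k-space + trajectory + coil maps: HDF5 (self-defined,
  ISMRMRD-inspired layout; angles in radians, lengths in mm, times in s);
* dynamic volumes: NIfTI (magnitude; optional phase companion), frames on
  the 4th axis, voxel size in the header (5 mm through-plane default);
* phantom ground truth: HDF5 companion;
* run configuration: YAML, hashed for provenance;
* findings and segment curves: CSV / JSON (written by the CLI).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .containers import DynamicVolume
from .encoding import CoilProfile, KSpaceSeries
from .phantom import (
    AIFParams,
    DefectSpec,
    GroundTruth,
    LVGeometry,
    MotionSpec,
    PhantomSpec,
    TissueParams,
    TriggerSpec,
)
from .recon import ReconConfig
from .sampling import SamplingPattern, build_pattern

SCHEMA_VERSION = "1"


class FormatError(RuntimeError):
    """A file does not match the expected layout; names the missing path."""


# ---------------------------------------------------------------------------
# raw k-space (HDF5)

def write_raw(path: str | Path, series: KSpaceSeries, coils: CoilProfile | None = None) -> Path:
    path = Path(path)
    p = series.pattern
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        ks = f.create_group("kspace")
        ks.create_dataset("data", data=series.data)
        ks.create_dataset("noise_sd", data=float(series.noise_sd))
        tr = f.create_group("traj")
        ang = tr.create_dataset("angles", data=p.angle_schedule)
        ang.attrs["units"] = "radians"
        tr.create_dataset("kz_order", data=p.kz_order)
        tr.attrs["n_readout"] = p.n_readout
        tr.attrs["k_max"] = p.k_max
        tr.attrs["oversampling"] = p.readout_oversampling
        tr.attrs["tr_ms"] = p.tr_ms
        if coils is not None:
            f.create_group("coils").create_dataset("maps", data=coils.maps)
    return path


def read_raw(path: str | Path) -> tuple[KSpaceSeries, CoilProfile | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("/kspace/data", "/traj/angles", "/traj/kz_order"):
            if name not in f:
                raise FormatError(f"missing dataset {name} in {path}")
        tr = f["traj"]
        angles = np.asarray(tr["angles"])
        pattern = SamplingPattern(
            n_readout=int(tr.attrs["n_readout"]),
            n_spokes_per_frame=angles.shape[1],
            n_frames=angles.shape[0],
            n_partitions=int(np.asarray(tr["kz_order"]).size),
            angle_schedule=angles,
            kz_order=np.asarray(tr["kz_order"]),
            k_max=float(tr.attrs["k_max"]),
            readout_oversampling=float(tr.attrs["oversampling"]),
            tr_ms=float(tr.attrs.get("tr_ms", 2.35)),
        )
        series = KSpaceSeries(
            data=np.asarray(f["kspace/data"]),
            pattern=pattern,
            noise_sd=float(np.asarray(f["kspace/noise_sd"])),
        )
        coils = None
        if "coils" in f and "maps" in f["coils"]:
            coils = CoilProfile(np.asarray(f["coils/maps"]))
    return series, coils


# ---------------------------------------------------------------------------
# dynamic volumes (NIfTI)

def write_volume(path: str | Path, volume: DynamicVolume, phase: bool = False) -> Path:
    """Write magnitude NIfTI (x, y, z, t axis order); optional phase companion."""
    path = Path(path)
    dzm, dym, dxm = volume.voxel_size_mm
    # (t, z, y, x) -> (x, y, z, t)
    arr = np.transpose(volume.magnitude, (3, 2, 1, 0)).astype(np.float32)
    affine = np.diag([dxm, dym, dzm, 1.0])
    img = nib.Nifti1Image(arr, affine)
    dt = float(np.mean(np.diff(volume.frame_times_s))) if volume.n_frames > 1 else 1.0
    img.header["pixdim"][4] = dt
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if phase:
        parr = np.transpose(np.angle(volume.data), (3, 2, 1, 0)).astype(np.float32)
        pimg = nib.Nifti1Image(parr, affine)
        stem = path.name.replace(".nii.gz", "").replace(".nii", "")
        nib.save(pimg, str(path.parent / f"{stem}_phase.nii"))
    return path


def read_volume(path: str | Path, provenance: str = "gridding") -> DynamicVolume:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise FormatError(f"expected a 4-D NIfTI at {path}, got {arr.ndim}-D")
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    data = np.transpose(arr, (3, 2, 1, 0)).astype(np.complex128)
    return DynamicVolume(
        data=data,
        voxel_size_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        frame_times_s=np.arange(data.shape[0]) * dt,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# ground truth (HDF5)

def write_ground_truth(path: str | Path, gt: GroundTruth) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("gt")
        g.create_dataset("labels", data=gt.labels)
        g.create_dataset("shifts", data=gt.shifts_mm)
        g.create_dataset("offsets", data=gt.trigger_offsets_s)
        g.create_dataset("flags", data=gt.mistrigger_flags.astype(np.uint8))
        g.create_dataset("frame_times", data=gt.frame_times_s)
        cg = g.create_group("curves")
        for name, c in gt.curves_mM.items():
            cg.create_dataset(name, data=c)
        sg = g.create_group("signals")
        for name, c in gt.signals.items():
            sg.create_dataset(name, data=c)
        g.attrs["voxel_mm"] = gt.voxel_mm
        g.attrs["endo_radius"] = gt.lv.endo_radius
        g.attrs["epi_radius"] = gt.lv.epi_radius
        g.attrs["long_axis_extent"] = gt.lv.long_axis_extent
        g.attrs["center_mm"] = gt.lv.center_mm
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "gt" not in f or "labels" not in f["gt"]:
            raise FormatError(f"missing dataset /gt/labels in {path}")
        g = f["gt"]
        lv = LVGeometry(
            endo_radius=float(g.attrs["endo_radius"]),
            epi_radius=float(g.attrs["epi_radius"]),
            long_axis_extent=float(g.attrs["long_axis_extent"]),
            center_mm=tuple(np.asarray(g.attrs["center_mm"], dtype=float)),
        )
        return GroundTruth(
            labels=np.asarray(g["labels"]),
            shifts_mm=np.asarray(g["shifts"]),
            trigger_offsets_s=np.asarray(g["offsets"]),
            mistrigger_flags=np.asarray(g["flags"]).astype(bool),
            curves_mM={k: np.asarray(v) for k, v in g["curves"].items()},
            signals={k: np.asarray(v) for k, v in g["signals"].items()},
            frame_times_s=np.asarray(g["frame_times"]),
            voxel_mm=tuple(np.asarray(g.attrs["voxel_mm"], dtype=float)),
            lv=lv,
        )


# ---------------------------------------------------------------------------
# run configuration (YAML)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_coils": 6,
    "noise_sd": 0.0,
    "n_edge_discard": 4,
    "phantom": {},  # PhantomSpec defaults
    "sampling": {},  # SamplingPattern defaults (16 partitions, 188 ms shot)
    "recon": {},  # ReconConfig defaults
    "analysis": {"threshold_frac": 0.15, "persist_min": 5, "artifact_window": 3},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def save_config(path: str | Path, config: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def phantom_spec_from_config(config: dict) -> PhantomSpec:
    ph = dict(config.get("phantom", {}))
    kwargs: dict = {}
    for key, cls in (
        ("lv", LVGeometry),
        ("aif", AIFParams),
        ("blood", TissueParams),
        ("myocardium", TissueParams),
        ("motion", MotionSpec),
        ("trigger", TriggerSpec),
    ):
        if key in ph:
            sub = ph.pop(key)
            if key == "lv" and "center_mm" in sub:
                sub["center_mm"] = tuple(sub["center_mm"])
            if key == "motion" and "amplitude_mm" in sub:
                sub["amplitude_mm"] = tuple(sub["amplitude_mm"])
            kwargs[key] = cls(**sub)
    if "defects" in ph:
        kwargs["defects"] = [DefectSpec(**d) for d in ph.pop("defects")]
    if "voxel_mm" in ph:
        ph["voxel_mm"] = tuple(ph["voxel_mm"])
    kwargs.update(ph)
    kwargs.setdefault("seed", config.get("seed", 0))
    return PhantomSpec(**kwargs)


def pattern_from_config(config: dict) -> SamplingPattern:
    return build_pattern(dict(config.get("sampling", {})))


def recon_config_from_config(config: dict) -> ReconConfig:
    return ReconConfig(**dict(config.get("recon", {})))


def config_roundtrip_equal(a: dict, b: dict) -> bool:
    return yaml.safe_dump(a, sort_keys=True) == yaml.safe_dump(b, sort_keys=True)


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["voxel_mm"] = list(d["voxel_mm"])
    d["lv"]["center_mm"] = list(d["lv"]["center_mm"])
    d["motion"]["amplitude_mm"] = list(d["motion"]["amplitude_mm"])
    return d
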