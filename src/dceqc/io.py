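"""Readers and writers: NIfTI volumes with sidecar manifests, AIF text
files, parameter-map and error-map outputs, and the run log.

Frame times and acquisition parameters live in a YAML sidecar manifest
rather than in NIfTI headers (header timing conventions vary across
dialects).  Masks are same-grid NIfTI volumes, value > 0 meaning inside.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .aif import ArterialInputFunction
from .signal import AcquisitionParams

__all__ = [
    "DynamicSeries",
    "read_dynamic_series",
    "write_dynamic_series",
    "read_mfa_series",
    "write_mfa_series",
    "read_mask",
    "write_volume",
    "read_aif",
    "write_aif",
    "write_outputs",
]


@dataclass
class DynamicSeries:
    """4-D dynamic signal series with frame times and acquisition params."""

    data: np.ndarray                # (x, y, z, t)
    times: np.ndarray               # s
    acq: AcquisitionParams
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("dynamic series must be 4-D")
        if self.data.shape[-1] != self.times.size:
            raise ValueError("frame count does not match times")


class FormatError(ValueError):
    """Input file or manifest does not match the expected layout."""


def _load_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _acq_from_manifest(m: dict, n_frames: int) -> AcquisitionParams:
    return AcquisitionParams(
        tr=float(m["tr"]), te=float(m.get("te", 1.7)),
        flip_angle=float(m["flip_angle"]),
        frame_interval=float(m["frame_interval"]), n_frames=n_frames)


def read_dynamic_series(nifti_path, manifest_path) -> DynamicSeries:
    """Load a 4-D NIfTI plus its YAML manifest (tr, te, flip_angle,
    frame_interval, n_frames, optional explicit frame_times)."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D series, got {data.ndim}-D")
    m = _load_manifest(manifest_path)
    if int(m["n_frames"]) != data.shape[-1]:
        raise FormatError(
            f"manifest n_frames={m['n_frames']} but series has {data.shape[-1]} frames")
    acq = _acq_from_manifest(m, data.shape[-1])
    times = (np.asarray(m["frame_times"], dtype=float)
             if "frame_times" in m else acq.frame_times)
    if times.size != data.shape[-1]:
        raise FormatError("frame_times length does not match the series")
    return DynamicSeries(data=data, times=times, acq=acq, affine=img.affine)


def write_dynamic_series(series: DynamicSeries, nifti_path, manifest_path) -> None:
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), series.affine),
             str(nifti_path))
    m = {
        "tr": series.acq.tr, "te": series.acq.te,
        "flip_angle": series.acq.flip_angle,
        "frame_interval": series.acq.frame_interval,
        "n_frames": int(series.data.shape[-1]),
        "frame_times": [float(t) for t in series.times],
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(m, fh, sort_keys=False)


def read_mfa_series(manifest_path):
    """Load a multi-flip-angle set: manifest lists one 3-D NIfTI per angle.

    Returns (stack (x,y,z,n_angles), flip_angles, tr, affine).
    """
    manifest_path = Path(manifest_path)
    m = _load_manifest(manifest_path)
    vols, angles = [], []
    affine = None
    for entry in m["files"]:
        img = nib.load(str(manifest_path.parent / entry["path"]))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 3:
            raise FormatError("MFA volumes must be 3-D")
        if affine is None:
            affine = img.affine
        elif vol.shape != vols[0].shape:
            raise FormatError("MFA volumes differ in grid")
        vols.append(vol)
        angles.append(float(entry["flip_angle"]))
    if len(vols) < 3:
        raise FormatError("need at least 3 flip angles")
    return np.stack(vols, axis=-1), np.array(angles), float(m["tr"]), affine


def write_mfa_series(stack, angles, tr, out_dir, affine=None, prefix="mfa") -> Path:
    """Write one 3-D NIfTI per flip angle plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    entries = []
    for i, a in enumerate(angles):
        name = f"{prefix}_fa{i:02d}.nii"
        nib.save(nib.Nifti1Image(np.asarray(stack[..., i], dtype=np.float32),
                                 affine), str(out_dir / name))
        entries.append({"path": name, "flip_angle": float(a)})
    manifest = out_dir / f"{prefix}_manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"tr": float(tr), "files": entries}, fh, sort_keys=False)
    return manifest


def read_mask(path, shape=None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if mask.ndim != 3:
        raise FormatError("mask must be 3-D")
    if shape is not None and mask.shape != tuple(shape):
        raise FormatError(f"mask grid {mask.shape} does not match {tuple(shape)}")
    return mask


def write_volume(data, path, affine=None, dtype=np.float32) -> Path:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))
    return Path(path)


def write_aif(aif: ArterialInputFunction, path) -> Path:
    """Serialize an AIF as two-column text with a provenance header."""
    path = Path(path)
    header = [f"# provenance: {aif.provenance}"]
    if aif.dose is not None:
        header.append(f"# dose_mmol_per_kg: {aif.dose}")
    header.append("# columns: time_s cp_mM")
    body = "\n".join(f"{t:.6f} {c:.8f}" for t, c in zip(aif.times, aif.cp))
    path.write_text("\n".join(header) + "\n" + body + "\n")
    return path


def read_aif(path) -> ArterialInputFunction:
    provenance, dose = "model", None
    times, cp = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "provenance:" in line:
                provenance = line.split("provenance:")[1].strip()
            elif "dose_mmol_per_kg:" in line:
                dose = float(line.split(":")[1])
            continue
        t, c = line.split()
        times.append(float(t))
        cp.append(float(c))
    return ArterialInputFunction(times=np.array(times), cp=np.array(cp),
                                 provenance=provenance, dose=dose)


def write_outputs(volume_results, error_map, out_dir, affine=None,
                  config=None, seed=None) -> dict:
    """Write parameter maps, the category map, PNG slices, the fit table and
    a run log; returns a manifest of written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written: dict[str, str] = {}
    for name, arr in volume_results.maps.as_dict().items():
        p = write_volume(arr, out_dir / f"{name}.nii", affine)
        written[name] = p.name
    p = write_volume(error_map.categories, out_dir / "error_categories.nii",
                     affine, dtype=np.int16)
    written["error_categories"] = p.name
    for png in error_map.save_slices_png(out_dir):
        written[png.stem] = png.name
    table_path = out_dir / "fit_table.tsv"
    volume_results.table.to_csv(table_path, sep="\t", index=False)
    written["fit_table"] = table_path.name

    log = {"tally": error_map.tally, "seed": seed}
    if config is not None:
        cfg = config.model_dump()
        log["config"] = cfg
        log["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        log["thresholds"] = cfg["thresholds"]
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    written["run_log"] = log_path.name
    manifest_path = out_dir / "outputs_manifest.json"
    manifest_path.write_text(json.dumps(written, indent=2))
    return written
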