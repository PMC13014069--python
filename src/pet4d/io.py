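"""File I/O: NIfTI images and masks, TAC/basis CSV, sinogram stacks, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import BasisSet, FrameSchedule
from .phantom import ScanGeometry, SinogramStack

__all__ = [
    "write_image", "read_image", "write_labels", "read_labels",
    "write_tac_csv", "read_tac_csv", "write_basis_csv",
    "write_sinogram_stack", "read_sinogram_stack", "write_manifest",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = voxel_size_mm
    return a


def write_image(path, data: np.ndarray, voxel_size_mm: float = 2.0) -> Path:
    """Write an image (2-D, 3-D, or 4-D frames-last) as float32 NIfTI."""
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))
    return path


def read_image(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def write_labels(path, labels: np.ndarray, voxel_size_mm: float = 2.0) -> Path:
    path = Path(path)
    arr = np.asarray(labels, dtype=np.int16)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_tac_csv(path, schedule: FrameSchedule, values: np.ndarray,
                  metadata: dict | None = None) -> Path:
    """TAC as CSV (frame_start, frame_end, value) with an optional JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"frame_start": schedule.frame_starts,
                  "frame_end": schedule.frame_ends,
                  "value": np.asarray(values, dtype=float)}).to_csv(path, index=False)
    if metadata:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2))
    return path


def read_tac_csv(path):
    df = pd.read_csv(path)
    sched = FrameSchedule(df["frame_start"].to_numpy(), df["frame_end"].to_numpy(),
                          np.ones(len(df), dtype=bool))
    return sched, df["value"].to_numpy()


def write_basis_csv(path, basis_set: BasisSet) -> Path:
    """Basis TACs as CSV (one column per basis) plus a JSON grid sidecar."""
    path = Path(path)
    cols = {"frame_start": basis_set.schedule.frame_starts,
            "frame_end": basis_set.schedule.frame_ends}
    for b in range(basis_set.n_bases):
        cols[f"basis_{b}"] = basis_set.basis_frames[b]
    pd.DataFrame(cols).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps({
        "k2_grid": basis_set.k2_grid.tolist(),
        "k2_min": basis_set.k2_min, "k2_max": basis_set.k2_max,
        "n_bases": basis_set.n_bases, "fine_dt": basis_set.fine_dt}, indent=2))
    return path


def write_sinogram_stack(path, stack: SinogramStack) -> Path:
    """Compressed binary counts with a JSON header (schedule, geometry, ids)."""
    path = Path(path)
    np.savez_compressed(path, counts=stack.counts, frame_scales=stack.frame_scales)
    g = stack.geometry
    header = {
        "frame_starts": stack.schedule.frame_starts.tolist(),
        "frame_ends": stack.schedule.frame_ends.tolist(),
        "fit_mask": stack.schedule.fit_mask.tolist(),
        "geometry": {"n_angles": g.n_angles, "n_bins": g.n_bins,
                     "psf_fwhm_mm": g.psf_fwhm_mm, "voxel_size_mm": g.voxel_size_mm,
                     "calibration": g.calibration},
        "image_size": stack.image_size, "count_level": stack.count_level,
        "subject_id": stack.subject_id, "replicate_id": stack.replicate_id,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path.with_suffix(".npz")


def read_sinogram_stack(path) -> SinogramStack:
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    header = json.loads(path.with_suffix(".json").read_text())
    sched = FrameSchedule(np.array(header["frame_starts"]),
                          np.array(header["frame_ends"]),
                          np.array(header["fit_mask"], dtype=bool))
    geom = ScanGeometry(**header["geometry"])
    return SinogramStack(counts=npz["counts"], schedule=sched, geometry=geom,
                         frame_scales=npz["frame_scales"],
                         image_size=header["image_size"],
                         count_level=header["count_level"],
                         subject_id=header["subject_id"],
                         replicate_id=header["replicate_id"])


def write_manifest(out_dir, files: list[Path], extra: dict | None = None) -> Path:
    """JSON manifest of artifacts with sha256 checksums."""
    out_dir = Path(out_dir)
    entries = []
    for f in files:
        f = Path(f)
        entries.append({"path": str(f.relative_to(out_dir)),
                        "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
                        "bytes": f.stat().st_size})
    manifest = {"artifacts": entries, **(extra or {})}
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p
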