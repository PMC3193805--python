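"""Readers and writers for the pipeline's on-disk formats.

Dynamic series, ROI masks and parameter maps travel as NIfTI (single-slice
grids stored as x, y, z=1[, t]); acquisition timing metadata as a JSON
sidecar; caliper tables and per-voxel fits as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import DCESeries, ParametricMap

__all__ = [
    "write_dce_series",
    "read_dce_series",
    "write_parameter_maps",
    "write_caliper_table",
    "read_caliper_table",
]

_AFFINE = np.eye(4)


def _as_nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), _AFFINE)


def write_dce_series(
    series: DCESeries, series_path: Path, mask_path: Path, timing_path: Path
) -> None:
    """Write a series as 4D NIfTI (rows, cols, 1, t), 0/1 mask, JSON timing."""
    series_path, mask_path, timing_path = map(Path, (series_path, mask_path, timing_path))
    vol = series.signal[:, :, None, :]
    nib.save(_as_nifti(vol), str(series_path))
    mask_img = nib.Nifti1Image(
        series.roi_mask[:, :, None].astype(np.int16), _AFFINE
    )
    nib.save(mask_img, str(mask_path))
    timing = {
        "frame_times_min": series.frame_times.tolist(),
        "n_baseline_frames": int(series.n_baseline_frames),
        "nominal_injection_duration_s": float(series.nominal_injection_duration),
        "actual_injection_duration_s": float(series.actual_injection_duration),
    }
    timing_path.write_text(json.dumps(timing, indent=2))


def read_dce_series(series_path: Path, mask_path: Path, timing_path: Path) -> DCESeries:
    signal = np.asarray(nib.load(str(series_path)).dataobj, dtype=float)
    if signal.ndim != 4 or signal.shape[2] != 1:
        raise ValueError("expected a 4D single-slice series (x, y, 1, t)")
    mask = np.asarray(nib.load(str(mask_path)).dataobj)
    if mask.ndim == 3:
        mask = mask[:, :, 0]
    timing = json.loads(Path(timing_path).read_text())
    return DCESeries(
        signal=signal[:, :, 0, :],
        frame_times=np.asarray(timing["frame_times_min"], dtype=float),
        n_baseline_frames=int(timing["n_baseline_frames"]),
        nominal_injection_duration=float(timing["nominal_injection_duration_s"]),
        actual_injection_duration=float(timing["actual_injection_duration_s"]),
        roi_mask=mask.astype(bool),
    )


def write_parameter_maps(pmap: ParametricMap, out_dir: Path, prefix: str = "") -> None:
    """Write A/k_ep/k_el/r2 NIfTI volumes, exclusion mask and per-voxel CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, data in (
        ("A", pmap.A),
        ("k_ep", pmap.k_ep),
        ("k_el", pmap.k_el),
        ("r2", pmap.r_squared),
    ):
        nib.save(_as_nifti(data[:, :, None]), str(out_dir / f"{prefix}{name}.nii.gz"))
    nib.save(
        nib.Nifti1Image(pmap.excluded[:, :, None].astype(np.int16), _AFFINE),
        str(out_dir / f"{prefix}excluded.nii.gz"),
    )
    pmap.to_dataframe().to_csv(out_dir / f"{prefix}voxel_fits.csv", index=False)


def write_caliper_table(frame: pd.DataFrame, path: Path) -> None:
    cols = ["tumor_id", "group", "day", "length_mm", "width_mm"]
    frame[cols].to_csv(path, index=False)


def read_caliper_table(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"tumor_id", "group", "day", "length_mm", "width_mm"} - set(frame.columns)
    if missing:
        raise ValueError(f"caliper table missing columns: {sorted(missing)}")
    return frame
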