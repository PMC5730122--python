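"""NIfTI volume and cohort-table input/output.

Volumes are NIfTI-1 files; all volumes of a run share one grid and are kept
in stored orientation (no reorientation — everything happens in a single
native space).  Cohort tables are CSV files with a header; an optional SPSS
``.sav`` dialect (for externally deposited per-subject tables) is available
when ``pyreadstat`` is installed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import SchemaError, ShapeError, VolumeParseError
from .grids import VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "COHORT_COLUMNS",
    "ASL_COLUMNS",
    "read_cohort",
    "write_cohort",
    "write_manifest",
    "read_manifest",
]


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeParseError(f"could not read NIfTI volume from {path}: {exc}") from exc
    return img


def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume.

    Raises
    ------
    VolumeParseError
        If the file is not a parseable NIfTI volume.
    ShapeError
        If the stored image is not 3-D.
    """
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(data, tuple(float(z) for z in zooms))


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a VolumeGrid as NIfTI-1, preserving dtype and voxel size."""
    img = nib.Nifti1Image(volume.data, _affine(volume.voxel_size))
    img.header.set_zooms(volume.voxel_size)
    img.header.set_data_dtype(volume.data.dtype)
    nib.save(img, str(path))


def read_series(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 4-D NIfTI series; returns (data, voxel_size)."""
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ShapeError(f"{path}: expected a 4-D series, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_series(data: np.ndarray, voxel_size: Sequence[float], path) -> None:
    data = np.asarray(data)
    if data.ndim != 4:
        raise ShapeError(f"expected a 4-D series, got ndim={data.ndim}")
    img = nib.Nifti1Image(data, _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size) + (1.0,))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: Canonical cohort schema: one row per subject.
COHORT_COLUMNS = [
    "subject_id",
    "age",                 # years
    "htn",                 # 0/1, on antihypertensive medication
    "dm",                  # 0/1, on diabetes medication
    "side_occluded",       # 'L' or 'R'
    "occlusion_complete",  # 1 = total occlusion, 0 = high-grade stenosis
    "collateral",          # cross-filling / none / unknown
    "m1_cbf_occ", "m1_cbf_unocc",      # ml*100g^-1*min^-1
    "v1_cbf_occ", "v1_cbf_unocc",
    "h_cbf_occ", "h_cbf_unocc",        # hemispheral GM CBF
    "m1_thick_occ", "m1_thick_unocc",  # mm
    "v1_thick_occ", "v1_thick_unocc",
    "wmh_occ", "wmh_unocc",            # WMH volume, deposited units
]

#: ASL-derived fields: a subject missing any of these is retained but flagged.
ASL_COLUMNS = [
    "m1_cbf_occ", "m1_cbf_unocc",
    "v1_cbf_occ", "v1_cbf_unocc",
    "h_cbf_occ", "h_cbf_unocc",
]

_MAX_THICKNESS_MM = 6.0


def _validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing mandatory columns: {missing}")
    thick_cols = [c for c in df.columns if "thick" in c]
    for c in thick_cols:
        vals = df[c].dropna()
        if ((vals <= 0) | (vals >= _MAX_THICKNESS_MM)).any():
            raise SchemaError(f"column {c}: thickness values must lie in (0, {_MAX_THICKNESS_MM}) mm")
    cbf_cols = [c for c in df.columns if "cbf" in c]
    for c in cbf_cols:
        if (df[c].dropna() < 0).any():
            raise SchemaError(f"column {c}: CBF values must be non-negative")
    df = df.copy()
    df["asl_missing"] = df[ASL_COLUMNS].isna().any(axis=1)
    return df


def read_cohort(path, dialect: str = "csv", mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-subject cohort table.

    Parameters
    ----------
    path : path-like
        CSV (default) or SPSS .sav file.
    dialect : {'csv', 'sav'}
        File dialect.  The 'sav' dialect needs the optional ``pyreadstat``
        backend.
    mapping : dict, optional
        Maps source column names to the canonical schema names, for files
        deposited under different headers.

    Returns
    -------
    DataFrame
        One record per subject.  Rows with any missing ASL-derived field are
        retained and flagged in the boolean ``asl_missing`` column, never
        silently dropped.
    """
    path = Path(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
            raise SchemaError(f"could not parse cohort CSV {path}: {exc}") from exc
    elif dialect == "sav":
        try:
            import pyreadstat  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "reading .sav cohort tables requires the optional pyreadstat "
                "backend (pip install perfcortex[sav])"
            ) from exc
        df = pd.read_spss(str(path))
    else:
        raise SchemaError(f"unknown cohort dialect {dialect!r}; use 'csv' or 'sav'")
    if mapping:
        df = df.rename(columns=dict(mapping))
    return _validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (full float precision, lossless round-trip)."""
    out = df.drop(columns=["asl_missing"], errors="ignore")
    out.to_csv(path, index=False, float_format="%.17g")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
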