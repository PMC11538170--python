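"""Reading and writing volumes, atlases, transforms and results tables.

NIfTI-1 is the sole volume dialect.  Affine transforms are serialized as
plain-text 4x4 matrices; deformation fields as 4D NIfTI volumes whose
last axis holds the 3-vector displacement in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .imaging_core import BinaryVOI, Grid, Volume


@dataclass
class LabelVolume:
    """Integer-labelled atlas on a grid; 0 is reserved for background."""

    labels: np.ndarray
    grid: Grid
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if np.any(self.labels < 0):
            raise ValueError("negative label ids are not allowed")
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}

    def ids_for(self, names) -> set[int]:
        """Atlas ids whose region name is in ``names`` (exact match)."""
        wanted = set(names)
        return {i for i, n in self.label_map.items() if n in wanted}

    def mask_for_ids(self, ids) -> np.ndarray:
        return np.isin(self.labels, sorted(ids))


def _grid_from_img(img) -> Grid:
    return Grid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine, float))


def read_volume(path) -> Volume:
    """Read a single-frame 3D NIfTI volume; reject 4D and non-finite data."""
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        data = np.asanyarray(img.dataobj)[..., 0]
    elif len(shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {len(shape)}D with "
            f"{shape[3] if len(shape) > 3 else '?'} frames"
        )
    else:
        data = np.asanyarray(img.dataobj)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume(data, _grid_from_img(img))


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.grid.affine)
    img.header.set_zooms(tuple(vol.grid.spacing))
    nib.save(img, str(path))


def write_mask(voi: BinaryVOI, path) -> None:
    img = nib.Nifti1Image(voi.mask.astype(np.uint8), voi.grid.affine)
    nib.save(img, str(path))


def read_mask(path, name: str = "voi") -> BinaryVOI:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return BinaryVOI(data > 0, _grid_from_img(img), name=name)


def read_label_map(path) -> dict[int, str]:
    """Read a region-name -> id table from JSON or two-column text."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
        # accept either {"name": id} or {"id": "name"} orientation
        out: dict[int, str] = {}
        for k, v in raw.items():
            if isinstance(v, (int, float)):
                out[int(v)] = str(k)
            else:
                out[int(k)] = str(v)
        return out
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, idx = line.split()[:2]
        out[int(idx)] = name
    return out


def write_label_map(label_map: dict[int, str], path) -> None:
    Path(path).write_text(
        json.dumps({name: idx for idx, name in sorted(label_map.items())}, indent=2)
    )


def read_label_volume(path, label_map_path) -> LabelVolume:
    """Read an integer atlas plus its label map; every nonzero id must be named."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    as_int = np.rint(data).astype(np.int64)
    if np.max(np.abs(data - as_int)) > 1e-6:
        raise ValueError(f"{path}: atlas voxel values are not integers")
    label_map = read_label_map(label_map_path)
    present = set(np.unique(as_int).tolist()) - {0}
    orphans = sorted(present - set(label_map))
    if orphans:
        raise ValueError(f"{path}: atlas ids missing from label map: {orphans}")
    return LabelVolume(as_int, _grid_from_img(img), label_map)


def write_label_volume(atlas: LabelVolume, path, label_map_path=None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    nib.save(img, str(path))
    if label_map_path is not None:
        write_label_map(atlas.label_map, label_map_path)


def write_affine_text(matrix: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(matrix, dtype=float), fmt="%.12g")


def read_affine_text(path) -> np.ndarray:
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def write_deformation(displacement_mm: np.ndarray, grid: Grid, path) -> None:
    """Write a (3, nx, ny, nz) mm displacement field as a 4D NIfTI."""
    arr = np.moveaxis(np.asarray(displacement_mm, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))


def read_deformation(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError(f"{path}: expected a 4D x/y/z displacement field")
    grid = Grid(tuple(int(s) for s in arr.shape[:3]), np.asarray(img.affine, float))
    return np.moveaxis(np.asarray(arr, np.float64), -1, 0), grid


#: column order of the per-subject ratios table
RATIOS_COLUMNS = [
    "subject",
    "mode",
    "region",
    "ratio_left",
    "ratio_right",
    "ratio_high",
    "ratio_low",
    "ai",
    "binding_ratio_left",
    "binding_ratio_right",
    "selected_w",
    "selected_w_left",
    "selected_w_right",
]


def write_ratios_table(rows: list[dict], path) -> pd.DataFrame:
    """Serialize quantification rows to CSV with a fixed column order.

    Floats are written at 6 significant digits; missing optional fields
    (e.g. selected weights in fixed-template mode) are left blank.
    """
    df = pd.DataFrame(rows)
    for col in RATIOS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RATIOS_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_ratios_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
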