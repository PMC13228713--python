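"""Reading and writing the package's on-disk formats.

Volumes travel as NIfTI-1 (nibabel), with acquisition metadata — echo
times, pixel geometry, label dictionaries — in JSON sidecars next to the
image file; measurement tables and contrast tables are plain CSV.
A multi-echo series may be stored either as one 4-D file or as one 3-D
file per echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import CartilageMask, EchoSeries, Grid, LaminarMask, T2Map

TABLE_COLUMNS = ["participant_id", "group", "time", "region", "layer", "value", "age", "bmi"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _nifti_affine(grid: Grid) -> np.ndarray:
    # data axes are (slice, row, col); nibabel stores axes in array order
    return grid.affine


def save_echo_series(series: EchoSeries, path: str | Path, split_echoes: bool = False) -> list[Path]:
    """Write an echo series as one 4-D NIfTI (default) or one file per
    echo, plus a JSON sidecar with echo times and voxel geometry.

    Returns the list of files written (sidecar last)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    affine = _nifti_affine(series.grid)
    if split_echoes:
        stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
        for k in range(series.n_echoes):
            p = path.with_name(f"{stem}_echo{k + 1}.nii")
            nib.save(nib.Nifti1Image(series.data[k], affine), p)
            written.append(p)
    else:
        # echo axis last in the file (x, y, z, echo) per NIfTI convention
        vol = np.moveaxis(series.data, 0, -1)
        nib.save(nib.Nifti1Image(vol, affine), path)
        written.append(path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "echo_times_ms": list(map(float, series.echo_times)),
                "pixel_size_mm": series.grid.pixel_size,
                "slice_thickness_mm": series.grid.slice_thickness,
                "split_echoes": split_echoes,
                "n_echoes": int(series.n_echoes),
            },
            indent=2,
        )
        + "\n"
    )
    written.append(sidecar)
    return written


def load_echo_series(path: str | Path) -> EchoSeries:
    """Load an echo series written by :func:`save_echo_series` (either
    layout), reading echo times from the sidecar."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    grid = None
    if meta.get("split_echoes"):
        stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
        vols = []
        for k in range(int(meta["n_echoes"])):
            img = nib.load(path.with_name(f"{stem}_echo{k + 1}.nii"))
            vols.append(np.asarray(img.dataobj, dtype=float))
            if grid is None:
                grid = Grid(meta["pixel_size_mm"], meta["slice_thickness_mm"], img.affine)
        data = np.stack(vols)
    else:
        img = nib.load(path)
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        grid = Grid(meta["pixel_size_mm"], meta["slice_thickness_mm"], img.affine)
    return EchoSeries(data, np.asarray(meta["echo_times_ms"], dtype=float), grid)


def save_mask(mask: CartilageMask, path: str | Path) -> list[Path]:
    """Write a label mask as integer NIfTI with its label dictionary in a
    JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), _nifti_affine(mask.grid)), path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "labels": {str(k): v for k, v in mask.region_names.items()},
                "pixel_size_mm": mask.grid.pixel_size,
                "slice_thickness_mm": mask.grid.slice_thickness,
            },
            indent=2,
        )
        + "\n"
    )
    return [path, sidecar]


def load_mask(path: str | Path) -> CartilageMask:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar_path(path).read_text())
    grid = Grid(meta["pixel_size_mm"], meta["slice_thickness_mm"], img.affine)
    labels = np.asarray(img.dataobj).astype(np.int16)
    names = {int(k): v for k, v in meta.get("labels", {}).items()}
    return CartilageMask(labels, grid, names)


def save_t2_map(t2map: T2Map, directory: str | Path, stem: str = "t2map") -> list[Path]:
    """Write T2, PD and validity volumes (``<stem>_t2/pd/valid.nii``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = _nifti_affine(t2map.grid)
    out = []
    for name, arr in (
        ("t2", t2map.t2),
        ("pd", t2map.pd),
        ("valid", t2map.valid.astype(np.int16)),
    ):
        p = directory / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(arr, affine), p)
        out.append(p)
    return out


def save_laminar_mask(lam: LaminarMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(lam.codes.astype(np.int16), _nifti_affine(lam.grid)), path)
    return path


def save_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement or contrast table as RFC 4180 CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\r\n", float_format="%.10g")
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
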