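"""Volume, basis and configuration IO.

Volumes are written as MetaImage (MHD + RAW) via SimpleITK.  Non-uniform
rectilinear volumes are resampled onto a uniform grid before export, with
the original axis coordinates recorded in a JSON sidecar.  Field bases are
persisted to HDF5 (one complex dataset per electrode plus grid metadata) so
plan re-evaluation needs no solver.  Run configurations are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import SimpleITK as sitk
import yaml

from .grid import RectilinearGrid
from .superposition import FieldBasis


def _is_uniform(coords: np.ndarray, tol: float = 1e-9) -> bool:
    d = np.diff(coords)
    return bool(np.all(np.abs(d - d[0]) <= tol * max(1.0, abs(d[0]))))


def export_volume(volume: np.ndarray, grid: RectilinearGrid, path, units: str | None = None,
                  spacing: float | None = None) -> Path:
    """Write a cell-centred volume to MetaImage with a JSON sidecar.

    Uniform grids are exported losslessly; non-uniform grids are linearly
    resampled to a uniform spacing (default: the finest step of each axis)
    and the original node coordinates are stored in the sidecar.
    """
    from .gamma import resample_to_uniform

    path = Path(path)
    volume = np.asarray(volume)
    uniform = all(_is_uniform(getattr(grid, a)) for a in "xyz")
    sidecar: dict = {"units": units, "native_grid_uniform": uniform}
    if uniform and spacing is None:
        arr = volume.astype(np.float32) if volume.dtype.kind == "f" else volume
        sp3 = [float(grid.steps(a)[0]) for a in "xyz"]
        origin = [float(getattr(grid, a)[0] + 0.5 * grid.steps(a)[0]) for a in "xyz"]
    else:
        sp_val = spacing if spacing is not None else min(float(grid.steps(a).min()) for a in "xyz")
        arr, origin_arr, spacing_arr = resample_to_uniform(
            volume.astype(float), grid, sp_val, grid.bounds
        )
        arr = arr.astype(np.float32)
        sp3 = [float(s) for s in spacing_arr]
        origin = [float(o + 0.5 * s) for o, s in zip(origin_arr, spacing_arr)]
        sidecar["native_node_coords_mm"] = {a: getattr(grid, a).tolist() for a in "xyz"}
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(sp3)
    img.SetOrigin(origin)
    sitk.WriteImage(img, str(path))
    sidecar["spacing_mm"] = sp3
    sidecar["origin_mm"] = origin
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def import_volume(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a MetaImage volume; returns (array[x,y,z], origin_mm, spacing_mm)."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, np.array(img.GetOrigin()), np.array(img.GetSpacing())


def save_basis(basis: FieldBasis, path) -> Path:
    """Persist a per-electrode field basis to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["reference_voltage"] = basis.reference_voltage
        f.attrs["frequency"] = basis.frequency
        f.attrs["n_electrodes"] = basis.n_electrodes
        for i, e in enumerate(basis.fields):
            f.create_dataset(f"E/{i}", data=e, compression="gzip", compression_opts=1)
        if basis.currents is not None:
            f.create_dataset("currents", data=basis.currents)
    return path


def load_basis(path) -> FieldBasis:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_electrodes"])
        fields = [f[f"E/{i}"][...] for i in range(n)]
        currents = f["currents"][...] if "currents" in f else None
        return FieldBasis(
            fields=fields,
            reference_voltage=float(f.attrs["reference_voltage"]),
            frequency=float(f.attrs["frequency"]),
            currents=currents,
        )


def save_grid(grid: RectilinearGrid, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({a: getattr(grid, a).tolist() for a in "xyz"}))
    return path


def load_grid(path) -> RectilinearGrid:
    d = json.loads(Path(path).read_text())
    return RectilinearGrid(x=np.array(d["x"]), y=np.array(d["y"]), z=np.array(d["z"]))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg
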