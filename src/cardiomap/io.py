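"""File round-tripping: CSV for per-cell fields and point tables, NPZ for
voxel stacks, YAML for configs.  Every writer/reader pair is an identity on
its data type."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .mri import TransmuralityPolarMap
from .noga import PolarMap
from .phantom import POINT_COLUMNS, LVPhantom, SliceStack

__all__ = [
    "write_phantom_csv", "read_phantom_csv",
    "write_points_csv", "read_points_csv",
    "write_polar_map_csv", "read_polar_map_csv",
    "save_stack_npz", "load_stack_npz",
]


def write_phantom_csv(phantom: LVPhantom, path) -> None:
    """Long-format per-cell table: slice, sector, wall, transmurality, segment."""
    s, k = np.divmod(np.arange(phantom.n_cells), phantom.n_sectors)
    df = pd.DataFrame({
        "slice_idx": s, "sector_idx": k,
        "wall_thickness_mm": phantom.wall_thickness_mm[s, k],
        "transmurality": phantom.transmurality_field[s, k],
        "segment12": phantom.segment12_labels[s, k],
    })
    with open(path, "w") as fh:
        fh.write(f"# seed={phantom.seed} slice_thickness_mm={phantom.slice_thickness_mm}"
                 f" r_endo_mm={phantom.r_endo_mm}\n")
        df.to_csv(fh, index=False)


def read_phantom_csv(path) -> LVPhantom:
    header = Path(path).read_text().splitlines()[0]
    if not header.startswith("#"):
        raise ConfigurationError("phantom CSV missing its metadata header")
    meta = dict(tok.split("=") for tok in header[1:].split())
    df = pd.read_csv(path, comment="#")
    n_slices = int(df["slice_idx"].max()) + 1
    n_sectors = int(df["sector_idx"].max()) + 1

    def grid(col, dtype=float):
        g = np.zeros((n_slices, n_sectors), dtype=dtype)
        g[df["slice_idx"], df["sector_idx"]] = df[col].to_numpy(dtype=dtype)
        return g

    return LVPhantom(
        n_slices=n_slices, n_sectors=n_sectors,
        wall_thickness_mm=grid("wall_thickness_mm"),
        transmurality_field=grid("transmurality"),
        segment12_labels=grid("segment12", int),
        seed=int(meta["seed"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        r_endo_mm=float(meta["r_endo_mm"]),
    )


def write_points_csv(points: pd.DataFrame, path) -> None:
    points[POINT_COLUMNS].to_csv(path, index=False)


def read_points_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POINT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"point table missing columns: {sorted(missing)}")
    return df[POINT_COLUMNS]


def write_polar_map_csv(pmap, path) -> None:
    """Grid long format with the validity mask; works for any polar map."""
    n_slices, n_sectors = pmap.values.shape
    s, k = np.divmod(np.arange(n_slices * n_sectors), n_sectors)
    df = pd.DataFrame({
        "slice_idx": s, "sector_idx": k,
        "value": pmap.values[s, k], "valid": pmap.valid[s, k].astype(int),
    })
    with open(path, "w") as fh:
        fh.write(f"# kind={pmap.kind}\n")
        df.to_csv(fh, index=False)


def read_polar_map_csv(path):
    header = Path(path).read_text().splitlines()[0]
    if not header.startswith("# kind="):
        raise ConfigurationError("polar map CSV missing its kind header")
    kind = header.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    n_slices = int(df["slice_idx"].max()) + 1
    n_sectors = int(df["sector_idx"].max()) + 1
    values = np.zeros((n_slices, n_sectors))
    valid = np.zeros((n_slices, n_sectors), dtype=bool)
    values[df["slice_idx"], df["sector_idx"]] = df["value"]
    valid[df["slice_idx"], df["sector_idx"]] = df["valid"].astype(bool)
    if kind == "transmurality":
        return TransmuralityPolarMap(values=values, valid=valid)
    return PolarMap(values=values, valid=valid, kind=kind)


def save_stack_npz(stack: SliceStack, path) -> None:
    np.savez_compressed(
        path, voxels=stack.voxels, voxel_mm=np.asarray(stack.voxel_mm),
        endo_mask=stack.endo_mask, epi_mask=stack.epi_mask,
        remote_mask=stack.remote_mask,
        n_slices=stack.n_slices, planes_per_slice=stack.planes_per_slice,
        true_scar_mask=(stack.true_scar_mask if stack.true_scar_mask is not None
                        else np.zeros((0,), dtype=bool)))


def load_stack_npz(path) -> SliceStack:
    with np.load(path) as z:
        true_scar = z["true_scar_mask"]
        return SliceStack(
            voxels=z["voxels"], voxel_mm=tuple(z["voxel_mm"]),
            endo_mask=z["endo_mask"], epi_mask=z["epi_mask"],
            remote_mask=z["remote_mask"], n_slices=int(z["n_slices"]),
            planes_per_slice=int(z["planes_per_slice"]),
            true_scar_mask=None if true_scar.size == 0 else true_scar)
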