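"""Container I/O: HDF5 named-array files plus a CSV metadata table.

No community standard exists for SORS line-scan cubes, so datasets are
stored as a directory ("container") holding ``data.h5`` — one group per
sample — and ``metadata.csv``.  Raw containers keep per-sample groups with
``cube`` (repeats x pixels x bands) and ``wavelength_nm`` arrays and
``laser_index`` / ``shrimp_id`` / ``day`` attributes; processed containers
keep ``matrix`` (bands x offsets), ``band_centers`` and ``offsets_mm``.
Round-trips are bit-exact (float64 throughout).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .preprocess import ProcessedSample
from .simulate import ScatterCube

RAW_ARRAYS = ("cube", "wavelength_nm")
RAW_ATTRS = ("laser_index", "shrimp_id", "day")
PROCESSED_ARRAYS = ("matrix", "band_centers", "offsets_mm")
PROCESSED_ATTRS = ("shrimp_id", "day")


def _group_name(sample_id: int) -> str:
    return f"sample_{sample_id:05d}"


def write_raw_container(cubes, metadata: pd.DataFrame, path: str | Path
                        ) -> Path:
    """Write scattering cubes (an iterable, consumed lazily) + metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "data.h5", "w") as f:
        for sample_id, cube in zip(metadata["sample_id"], cubes):
            g = f.create_group(_group_name(int(sample_id)))
            g.create_dataset("cube", data=cube.data)
            g.create_dataset("wavelength_nm", data=cube.wavelength_axis)
            g.attrs["laser_index"] = int(cube.laser_index)
            g.attrs["shrimp_id"] = int(cube.shrimp_id)
            g.attrs["day"] = int(cube.day)
    metadata.to_csv(path / "metadata.csv", index=False)
    return path


def read_raw_container(path: str | Path) -> tuple[list[ScatterCube], pd.DataFrame]:
    path = Path(path)
    metadata = _read_metadata(path)
    cubes = []
    with h5py.File(path / "data.h5", "r") as f:
        for sample_id in metadata["sample_id"]:
            g = _get_group(f, int(sample_id))
            _require(g, RAW_ARRAYS, RAW_ATTRS)
            cubes.append(ScatterCube(
                data=g["cube"][()],
                wavelength_axis=g["wavelength_nm"][()],
                laser_index=int(g.attrs["laser_index"]),
                shrimp_id=int(g.attrs["shrimp_id"]),
                day=int(g.attrs["day"])))
    return cubes, metadata


def write_processed_container(samples: list[ProcessedSample],
                              metadata: pd.DataFrame, path: str | Path
                              ) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "data.h5", "w") as f:
        for sample_id, s in zip(metadata["sample_id"], samples):
            g = f.create_group(_group_name(int(sample_id)))
            g.create_dataset("matrix", data=s.matrix)
            g.create_dataset("band_centers", data=s.band_centers)
            g.create_dataset("offsets_mm", data=s.offsets_mm)
            g.attrs["shrimp_id"] = int(s.shrimp_id)
            g.attrs["day"] = int(s.day)
    metadata.to_csv(path / "metadata.csv", index=False)
    return path


def read_processed_container(path: str | Path
                             ) -> tuple[list[ProcessedSample], pd.DataFrame]:
    path = Path(path)
    metadata = _read_metadata(path)
    samples = []
    with h5py.File(path / "data.h5", "r") as f:
        for sample_id in metadata["sample_id"]:
            g = _get_group(f, int(sample_id))
            _require(g, PROCESSED_ARRAYS, PROCESSED_ATTRS)
            samples.append(ProcessedSample(
                matrix=g["matrix"][()],
                band_centers=g["band_centers"][()],
                offsets_mm=g["offsets_mm"][()],
                shrimp_id=int(g.attrs["shrimp_id"]),
                day=int(g.attrs["day"])))
    return samples, metadata


def _read_metadata(path: Path) -> pd.DataFrame:
    csv = path / "metadata.csv"
    if not csv.exists():
        raise SchemaError(f"container {path} is missing metadata.csv")
    meta = pd.read_csv(csv)
    for col in ("sample_id", "shrimp_id", "day"):
        if col not in meta.columns:
            raise SchemaError(f"metadata.csv is missing column {col!r}")
    return meta


def _get_group(f: h5py.File, sample_id: int) -> h5py.Group:
    name = _group_name(sample_id)
    if name not in f:
        raise SchemaError(f"container is missing group {name!r}")
    return f[name]


def _require(g: h5py.Group, arrays, attrs) -> None:
    for a in arrays:
        if a not in g:
            raise SchemaError(f"group {g.name!r} is missing array {a!r}")
    for a in attrs:
        if a not in g.attrs:
            raise SchemaError(f"group {g.name!r} is missing attribute {a!r}")
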