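"""Readers and writers: NIfTI volumes, TSV tables, parcellation serialization.

TSV (tab-separated, header row, UTF-8) is the exchange format for all
tables; NIfTI-1 for all volumes. Voxel indexing is 0-based internally and
the NIfTI affine is preserved round-trip.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_volume",
    "check_same_grid",
    "read_table",
    "write_table",
    "write_connectivity",
    "read_connectivity",
    "write_parcellation_tsv",
    "read_parcellation_tsv",
    "parcellation_to_volume",
    "sha256_of",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, 4x4 affine)."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises several header-specific types
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    return data, affine


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)  # NIfTI-1 has no portable 64-bit int
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_label_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load an integer label volume; non-integer voxel values are a type error."""
    data, affine = read_volume(path)
    if not np.all(np.equal(np.mod(data, 1), 0)):
        raise TypeError(f"{path} contains non-integer values; not a label volume")
    return data.astype(int), affine


def check_same_grid(volumes: list[tuple[np.ndarray, np.ndarray]]) -> None:
    """Raise if the volumes differ in shape or affine (grid mismatch)."""
    if not volumes:
        return
    shape0, aff0 = volumes[0][0].shape, volumes[0][1]
    for i, (data, aff) in enumerate(volumes[1:], start=1):
        if data.shape != shape0 or not np.allclose(aff, aff0):
            raise ValueError(f"volume {i} is on a different grid than volume 0")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_connectivity(conn, path) -> None:
    """Write a connectivity-profile matrix as TSV (rows = seed voxels)."""
    df = pd.DataFrame(conn.counts,
                      columns=[f"target_{t}" for t in conn.target_ids])
    df.insert(0, "seed_id", conn.seed_ids)
    write_table(df, path)


def read_connectivity(path):
    from .parcellation import ConnectivityProfileMatrix

    df = read_table(path)
    target_cols = [c for c in df.columns if c.startswith("target_")]
    return ConnectivityProfileMatrix(
        counts=df[target_cols].to_numpy(dtype=float),
        seed_ids=df["seed_id"].to_numpy(),
        target_ids=np.array([int(c.removeprefix("target_")) for c in target_cols]))


def write_parcellation_tsv(parc, seed_ids, path) -> None:
    labels = parc.labels if hasattr(parc, "labels") else np.asarray(parc)
    write_table(pd.DataFrame({"voxel_id": seed_ids, "label": labels}), path)


def read_parcellation_tsv(path):
    from .parcellation import Parcellation

    df = read_table(path)
    labels = df["label"].to_numpy(dtype=int)
    return Parcellation(labels=labels, k=len(np.unique(labels))), \
        df["voxel_id"].to_numpy()


def parcellation_to_volume(labels: np.ndarray, coords: np.ndarray,
                           pad: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize voxel labels into an integer NIfTI-ready label volume.

    Builds the bounding-box grid of ``coords`` (plus ``pad`` background
    voxels on each side), places each voxel's label, and returns the volume
    with an affine translating grid indices back to the original integer
    coordinates. Background is 0.
    """
    coords = np.asarray(coords, dtype=int)
    origin = coords.min(axis=0) - pad
    shape = coords.max(axis=0) - origin + 1 + pad
    vol = np.zeros(tuple(shape), dtype=np.int16)
    ijk = coords - origin
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = labels
    affine = np.eye(4)
    affine[:3, 3] = origin
    return vol, affine


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
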