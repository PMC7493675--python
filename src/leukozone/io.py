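"""Volume and table IO.

Volumes travel as NIfTI (.nii / .nii.gz) via nibabel; voxel spacing is
taken from the header zooms. Tables are tab-delimited text with a
commented header block recording the generating seed and config hash,
so every artifact is self-describing and reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import Volume


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI volume; rejects non-3-D data and bad spacing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"{path}: non-finite or non-positive voxel spacing {spacing}")
    return Volume(data, spacing)


def write_volume(volume: Volume, path: str | Path, dtype=None) -> Path:
    """Write a volume as NIfTI with a diagonal affine built from spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if dtype is None:
        dtype = np.uint8 if data.dtype == bool else data.dtype
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                config: dict | None = None) -> Path:
    """Write a TSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ["# leukozone table"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config is not None:
        header.append(f"# config_hash={config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
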