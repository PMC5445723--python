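"""Readers and writers: NIfTI series, bvals/bvecs, slice-order files,
motion tables, YAML configuration and provenance records.

Index conventions: slice and volume indices are 0-based everywhere;
the slice axis is assumed to be the third voxel axis of the image
(standard axial DWI); world coordinates follow the NIfTI affine.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .scheme import DiffusionScheme
from .temporal import SliceTiming

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_slice_order",
    "write_slice_order",
    "read_motion_table",
    "write_motion_table",
    "load_config",
    "write_provenance",
]


def read_dwi(path, bvals_path, bvecs_path):
    """Load a 4D NIfTI series and its FSL-style diffusion scheme.

    Returns ``(data, affine, scheme)`` with data as float64 of shape
    (n_vols, nx, ny, nz) — the volume index first, matching the rest of
    the package.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    scheme = DiffusionScheme.from_files(bvals_path, bvecs_path)
    if data.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"{path}: {data.shape[3]} volumes but scheme lists "
            f"{scheme.n_volumes}"
        )
    return np.moveaxis(data, -1, 0), img.affine.copy(), scheme


def write_dwi(path, series, affine=None):
    """Write a (n_vols, nx, ny, nz) series as 4D NIfTI."""
    series = np.asarray(series)
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.moveaxis(series, 0, -1).astype(np.float32), affine)
    nib.save(img, str(path))


def read_slice_order(path, n_slices: int, mb_factor: int = 1) -> SliceTiming:
    """Slice-timing from a file: the keywords ``sequential`` /
    ``interleaved`` or one line per excitation time of comma-separated
    0-based slice indices."""
    text = Path(path).read_text().strip()
    first = text.splitlines()[0].strip().lower() if text else ""
    if first in ("sequential", "interleaved"):
        ctor = getattr(SliceTiming, first)
        return ctor(n_slices, mb_factor)
    groups = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        groups.append(tuple(int(tok) for tok in line.replace(",", " ").split()))
    return SliceTiming.explicit(groups, n_slices=n_slices)


def write_slice_order(path, timing: SliceTiming):
    lines = [",".join(str(s) for s in g) for g in timing.groups]
    Path(path).write_text("\n".join(lines) + "\n")


def write_motion_table(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_motion_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_provenance(path, seed, config: dict | None = None, **extra):
    """Machine-readable run record: config hash, seed and versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    record = {
        "s2v_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
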