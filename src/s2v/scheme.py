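"""Diffusion scheme handling: b-values, gradient directions, shell grouping.

Reads and writes FSL-style ``bvals``/``bvecs`` text files (one row of
b-values; three rows of direction components, one column per volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiffusionDescriptor", "DiffusionScheme"]

#: b-values at or below this (s/mm^2) are treated as b=0.
B0_THRESHOLD = 50.0

#: relative tolerance for grouping b-values into shells.
SHELL_TOL = 0.10


@dataclass(frozen=True)
class DiffusionDescriptor:
    """Magnitude and direction of diffusion weighting for one volume.

    ``bval`` in s/mm^2; ``bvec`` a unit 3-vector (arbitrary for b=0).
    """

    bval: float
    bvec: np.ndarray

    def __post_init__(self):
        b = float(self.bval)
        if not np.isfinite(b) or b < 0:
            raise ValueError(f"b-value must be finite and >= 0, got {b}")
        g = np.asarray(self.bvec, dtype=float).reshape(3)
        if b > B0_THRESHOLD:
            n = np.linalg.norm(g)
            if abs(n - 1.0) > 1e-8:
                if n == 0:
                    raise ValueError("zero gradient direction for b > 0")
                g = g / n
        object.__setattr__(self, "bval", b)
        object.__setattr__(self, "bvec", g)


@dataclass
class DiffusionScheme:
    """b-values and unit gradient directions for a 4D series.

    ``bvals``: (n,) array; ``bvecs``: (n, 3) array of unit vectors
    (zero rows allowed for b=0 volumes).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray = field(init=False)
    shell_bvals: np.ndarray = field(init=False)

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        g = np.asarray(self.bvecs, dtype=float)
        if g.shape == (3, b.size) and g.shape[0] != g.shape[1]:
            g = g.T
        if g.shape != (b.size, 3):
            raise ValueError(
                f"bvecs shape {g.shape} inconsistent with {b.size} b-values"
            )
        norms = np.linalg.norm(g, axis=1)
        dwi = b > B0_THRESHOLD
        bad = dwi & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            warnings.warn(
                f"{bad.sum()} non-unit gradient directions normalised",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(norms[:, None] > 0, g / np.where(norms == 0, 1, norms)[:, None], g)
        self.bvals = b
        self.bvecs = g
        self.shell_ids, self.shell_bvals = _group_shells(b)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def descriptor(self, i: int) -> DiffusionDescriptor:
        return DiffusionDescriptor(self.bvals[i], self.bvecs[i])

    def shells(self) -> dict[float, np.ndarray]:
        """Map of shell centre b-value -> volume indices (including b=0)."""
        out = {}
        for sid in np.unique(self.shell_ids):
            idx = np.flatnonzero(self.shell_ids == sid)
            out[float(self.shell_bvals[sid])] = idx
        return out

    @classmethod
    def from_files(cls, bvals_path, bvecs_path) -> "DiffusionScheme":
        bvals = np.loadtxt(bvals_path).reshape(-1)
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.ndim != 2 or 3 not in bvecs.shape:
            raise ValueError(f"bvecs file must be 3xN or Nx3, got {bvecs.shape}")
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        if bvecs.shape[0] != bvals.size:
            raise ValueError(
                f"bvals count ({bvals.size}) != bvecs count ({bvecs.shape[0]})"
            )
        return cls(bvals, bvecs)

    def to_files(self, bvals_path, bvecs_path) -> None:
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%.8f")


def _group_shells(bvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cluster b-values into shells at 10% relative tolerance.

    b=0 (anything <= B0_THRESHOLD) is always its own group with id 0.
    """
    ids = np.full(bvals.size, -1, dtype=int)
    centres = [0.0]
    ids[bvals <= B0_THRESHOLD] = 0
    for i in np.argsort(bvals):
        if ids[i] >= 0:
            continue
        b = bvals[i]
        for sid, c in enumerate(centres):
            if sid == 0:
                continue
            if abs(b - c) <= SHELL_TOL * c:
                ids[i] = sid
                break
        else:
            centres.append(b)
            ids[i] = len(centres) - 1
    # refine centres to the member mean
    centres = np.array(
        [
            bvals[ids == sid].mean() if np.any(ids == sid) else c
            for sid, c in enumerate(centres)
        ]
    )
    centres[0] = 0.0
    return ids, centres
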