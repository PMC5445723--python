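"""Rigid-body parametrisation and homogeneous transforms.

Conventions (fixed and shared by the simulator, the estimator and the
evaluator, which is all that matters for self-consistency):

* six parameters ``(dx, dy, dz, phi_x, phi_y, phi_z)`` — translations in
  mm, rotations in radians (degrees only at I/O boundaries);
* rotations are extrinsic about the world axes, applied in x, then y,
  then z order;
* the world frame has its origin at the volume centre (mm), so rotations
  are about the volume centre, which minimises translation/rotation
  coupling;
* a point is transformed translation-first: ``x' = Rz Ry Rx (x + t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidParams",
    "make_rigid_matrix",
    "invert_rigid",
    "voxel_world_maps",
    "check_rigid_matrix",
]

_ORTHO_TOL = 1e-9


def _wrap_angle(a: float) -> float:
    """Wrap an angle to the half-open interval (-pi, pi]."""
    a = float(a)
    w = np.remainder(a + np.pi, 2.0 * np.pi) - np.pi
    if w == -np.pi:
        w = np.pi
    return w


@dataclass(frozen=True)
class RigidParams:
    """Six rigid-body movement parameters at one time point.

    Translations ``dx, dy, dz`` in mm; rotations ``phi_x, phi_y, phi_z``
    in radians, wrapped to (-pi, pi].
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    phi_x: float = 0.0
    phi_y: float = 0.0
    phi_z: float = 0.0

    def __post_init__(self):
        vals = (self.dx, self.dy, self.dz, self.phi_x, self.phi_y, self.phi_z)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"rigid parameters must be finite, got {vals}")
        object.__setattr__(self, "dx", float(self.dx))
        object.__setattr__(self, "dy", float(self.dy))
        object.__setattr__(self, "dz", float(self.dz))
        object.__setattr__(self, "phi_x", _wrap_angle(self.phi_x))
        object.__setattr__(self, "phi_y", _wrap_angle(self.phi_y))
        object.__setattr__(self, "phi_z", _wrap_angle(self.phi_z))

    @classmethod
    def from_array(cls, a) -> "RigidParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {a.shape}")
        return cls(*a)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.dx, self.dy, self.dz, self.phi_x, self.phi_y, self.phi_z]
        )


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def make_rigid_matrix(r: RigidParams) -> np.ndarray:
    """One-augmented 4x4 transform for rigid parameters ``r``.

    Applying the matrix to a one-augmented world point gives
    ``x' = Rz Ry Rx (x + t)`` (translation then rotation, extrinsic
    x -> y -> z about the world origin, i.e. the volume centre).
    """
    if not isinstance(r, RigidParams):
        r = RigidParams.from_array(np.asarray(r, dtype=float))
    rot = _rot_z(r.phi_z) @ _rot_y(r.phi_y) @ _rot_x(r.phi_x)
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = rot @ np.array([r.dx, r.dy, r.dz])
    return m


def check_rigid_matrix(m: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    """Validate a 4x4 rigid matrix (bottom row, orthonormality, det +1)."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("rigid matrix contains non-finite entries")
    if not np.allclose(m[3], [0, 0, 0, 1], atol=tol):
        raise ValueError(f"bottom row is not (0,0,0,1): {m[3]}")
    rot = m[:3, :3]
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-7):
        raise ValueError("rotation block is not orthonormal")
    if abs(np.linalg.det(rot) - 1.0) > 1e-7:
        raise ValueError("rotation block determinant is not +1")


def invert_rigid(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a rigid 4x4 transform."""
    check_rigid_matrix(m)
    rot = m[:3, :3]
    inv = np.eye(4)
    inv[:3, :3] = rot.T
    inv[:3, 3] = -rot.T @ m[:3, 3]
    return inv


def voxel_world_maps(shape, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Affine maps between voxel indices and world mm coordinates.

    The world origin sits at the volume centre ``(shape - 1) / 2`` in
    voxel coordinates, and the slice axis is the third voxel axis.
    Returns ``(vox2world, world2vox)``, mutual inverses.
    """
    shape = np.asarray(shape, dtype=float)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if shape.shape != (3,) or np.any(shape <= 0):
        raise ValueError(f"grid shape must be three positive dims, got {shape}")
    if np.any(voxel_size <= 0) or not np.all(np.isfinite(voxel_size)):
        raise ValueError(f"voxel sizes must be positive, got {voxel_size}")
    centre = (shape - 1.0) / 2.0
    vox2world = np.eye(4)
    vox2world[:3, :3] = np.diag(voxel_size)
    vox2world[:3, 3] = -voxel_size * centre
    world2vox = np.eye(4)
    world2vox[:3, :3] = np.diag(1.0 / voxel_size)
    world2vox[:3, 3] = centre
    return vox2world, world2vox


def apply_transform(m: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to points of shape (..., 3)."""
    pts = np.asarray(pts, dtype=float)
    return pts @ m[:3, :3].T + m[:3, 3]
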