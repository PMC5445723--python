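"""Temporal movement model: DCT basis over excitation time, slice timing.

Within one volume acquired at N discrete excitation times, each of the
six rigid-body parameters is a truncated discrete-cosine series

    r_p(n) = sum_{k=0..M} B[k, p] * cos(k * n * pi / (N - 1)),

so M = 0 reverts to the usual no-intra-volume-movement (volumetric)
model.  A slice-timing table Z maps each excitation time index to the
set of slice indices excited at that time (one slice for single-band,
an MB group for multi-band); all slices of one group share movement
parameters.

The temporal regularisation penalises the summed squared analytical
second derivative of r(t) at the integer time points, expressible as a
quadratic form in the coefficient matrix B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidParams

__all__ = [
    "DCTMovementModel",
    "SliceTiming",
    "dct_design_row",
    "dct_design_matrix",
    "movement_at_time",
    "movement_for_slice",
    "penalty_matrix",
    "second_derivative_penalty",
    "apply_shape_reference",
]


def dct_design_row(n: int, N: int, M: int) -> np.ndarray:
    """Row of the DCT design at time index ``n``: element k is cos(k n pi/(N-1))."""
    if N < 2:
        raise ValueError(f"need at least 2 excitation times, got N={N}")
    if not 0 <= n <= N - 1:
        raise ValueError(f"time index {n} outside [0, {N - 1}]")
    if not 0 <= M <= N - 1:
        raise ValueError(f"DCT order M={M} must satisfy 0 <= M <= N-1={N - 1}")
    k = np.arange(M + 1)
    return np.cos(k * n * np.pi / (N - 1))


def dct_design_matrix(N: int, M: int) -> np.ndarray:
    """(N, M+1) design with rows ``dct_design_row(n, N, M)``."""
    if N < 2:
        raise ValueError(f"need at least 2 excitation times, got N={N}")
    if not 0 <= M <= N - 1:
        raise ValueError(f"DCT order M={M} must satisfy 0 <= M <= N-1={N - 1}")
    n = np.arange(N)[:, None]
    k = np.arange(M + 1)[None, :]
    return np.cos(k * n * np.pi / (N - 1))


@dataclass
class DCTMovementModel:
    """DCT coefficients of the six movement parameters for one volume.

    ``coeffs`` is (M+1, 6): row 0 the constant term; columns are
    (dx, dy, dz, phi_x, phi_y, phi_z) in mm and radians.
    """

    coeffs: np.ndarray
    n_times: int

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 2 or c.shape[1] != 6:
            raise ValueError(f"coeffs must be (M+1, 6), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        if self.n_times < 2:
            raise ValueError("n_times must be >= 2")
        if c.shape[0] > self.n_times:
            raise ValueError(
                f"order M={c.shape[0] - 1} exceeds N-1={self.n_times - 1}"
            )
        self.coeffs = c

    @property
    def order(self) -> int:
        return self.coeffs.shape[0] - 1

    @classmethod
    def zeros(cls, order: int, n_times: int) -> "DCTMovementModel":
        return cls(np.zeros((order + 1, 6)), n_times)

    @classmethod
    def constant(cls, r: RigidParams, n_times: int, order: int = 0) -> "DCTMovementModel":
        c = np.zeros((order + 1, 6))
        c[0] = r.to_array()
        return cls(c, n_times)

    @classmethod
    def fit_trace(cls, trace: np.ndarray, order: int) -> "DCTMovementModel":
        """Least-squares DCT fit to an (N, 6) per-excitation parameter trace."""
        trace = np.asarray(trace, dtype=float)
        N = trace.shape[0]
        C = dct_design_matrix(N, order)
        coeffs, *_ = np.linalg.lstsq(C, trace, rcond=None)
        return cls(coeffs, N)

    def trace(self) -> np.ndarray:
        """Evaluate the model at every time index; (N, 6)."""
        return dct_design_matrix(self.n_times, self.order) @ self.coeffs

    def copy(self) -> "DCTMovementModel":
        return DCTMovementModel(self.coeffs.copy(), self.n_times)


def movement_at_time(model: DCTMovementModel, n: int) -> RigidParams:
    """Rigid parameters at excitation time index ``n``."""
    row = dct_design_row(n, model.n_times, model.order)
    return RigidParams.from_array(row @ model.coeffs)


@dataclass
class SliceTiming:
    """Map from excitation time index to the slice indices excited then.

    ``groups[n]`` is the tuple of slice indices acquired at time n; the
    groups partition {0, ..., n_slices-1}.  For multi-band, each group
    has ``mb_factor`` members (the last may be smaller for explicit
    tables).
    """

    n_slices: int
    mb_factor: int
    groups: list = field(default_factory=list)
    ordering: str = "explicit"

    def __post_init__(self):
        groups = [tuple(int(s) for s in g) for g in self.groups]
        flat = [s for g in groups for s in g]
        if sorted(flat) != list(range(self.n_slices)):
            seen = set()
            dupes = sorted({s for s in flat if s in seen or seen.add(s)})
            missing = sorted(set(range(self.n_slices)) - set(flat))
            raise ValueError(
                "slice-timing groups must partition the slices; "
                f"duplicates={dupes}, missing={missing}"
            )
        if self.ordering != "explicit":
            if any(len(g) != self.mb_factor for g in groups):
                raise ValueError("all groups must have mb_factor slices")
        elif any(len(g) > self.mb_factor for g in groups):
            raise ValueError("a group exceeds the multi-band factor")
        self.groups = groups
        lut = np.empty(self.n_slices, dtype=int)
        for n, g in enumerate(groups):
            for s in g:
                lut[s] = n
        self._slice_to_time = lut

    @property
    def n_times(self) -> int:
        return len(self.groups)

    def time_of_slice(self, s: int) -> int:
        if not 0 <= s < self.n_slices:
            raise ValueError(f"slice index {s} outside [0, {self.n_slices - 1}]")
        return int(self._slice_to_time[s])

    @property
    def slice_to_time(self) -> np.ndarray:
        return self._slice_to_time.copy()

    @classmethod
    def sequential(cls, n_slices: int, mb_factor: int = 1) -> "SliceTiming":
        groups = _mb_groups(n_slices, mb_factor)
        return cls(n_slices, mb_factor, groups, ordering="sequential")

    @classmethod
    def interleaved(cls, n_slices: int, mb_factor: int = 1) -> "SliceTiming":
        """Odd/even two-pass order: groups 0, 2, 4, ..., 1, 3, 5, ..."""
        base = _mb_groups(n_slices, mb_factor)
        order = list(range(0, len(base), 2)) + list(range(1, len(base), 2))
        return cls(n_slices, mb_factor, [base[i] for i in order], ordering="interleaved")

    @classmethod
    def explicit(cls, groups, n_slices: int | None = None) -> "SliceTiming":
        groups = [tuple(g) for g in groups]
        if n_slices is None:
            n_slices = sum(len(g) for g in groups)
        mb = max(len(g) for g in groups)
        return cls(n_slices, mb, groups, ordering="explicit")


def _mb_groups(n_slices: int, mb_factor: int) -> list[tuple[int, ...]]:
    """Spatial MB groups in ascending leader order: group g = {g + k*n_groups}."""
    if n_slices <= 0 or mb_factor <= 0:
        raise ValueError("n_slices and mb_factor must be positive")
    if n_slices % mb_factor:
        raise ValueError(
            f"{n_slices} slices not divisible by MB factor {mb_factor}; "
            "use an explicit slice-timing table"
        )
    n_groups = n_slices // mb_factor
    return [tuple(g + k * n_groups for k in range(mb_factor)) for g in range(n_groups)]


def movement_for_slice(
    model: DCTMovementModel, timing: SliceTiming, s: int
) -> RigidParams:
    """Rigid parameters for slice ``s``: those of its excitation time."""
    if timing.n_times != model.n_times:
        raise ValueError(
            f"timing has {timing.n_times} times but model has {model.n_times}"
        )
    return movement_at_time(model, timing.time_of_slice(s))


def penalty_matrix(N: int, M: int) -> np.ndarray:
    """Quadratic-form matrix P of the second-derivative penalty.

    The penalty for one parameter with coefficient vector b is
    ``b.T @ P @ b = sum_n r''(n)^2`` where the second derivative of each
    cosine basis function is taken analytically in time-index units.
    """
    n = np.arange(N)[:, None]
    k = np.arange(M + 1)[None, :]
    w = k * np.pi / (N - 1)
    C2 = -(w**2) * np.cos(w * n)
    return C2.T @ C2


def second_derivative_penalty(model: DCTMovementModel) -> float:
    """Summed squared analytical second temporal derivative of r(t).

    Sum over integer time points and the six parameters (mm and radian
    units as stored); zero iff all non-constant coefficients vanish.
    """
    P = penalty_matrix(model.n_times, model.order)
    return float(np.einsum("kp,kl,lp->", model.coeffs, P, model.coeffs))


def apply_shape_reference(models, ref_index: int):
    """Regress the reference volume's intra-volume terms out of all volumes.

    The non-constant coefficient rows (1..M) of the reference model are
    subtracted from every model; the reference becomes constant-only.
    Returns a new list; inputs are not modified.
    """
    models = list(models)
    if not models:
        return []
    M = models[0].order
    N = models[0].n_times
    for m in models:
        if m.order != M or m.n_times != N:
            raise ValueError("all models must share the same order and n_times")
    if not 0 <= ref_index < len(models):
        raise ValueError(f"reference index {ref_index} out of range")
    if M == 0:
        return [m.copy() for m in models]
    ref_rows = models[ref_index].coeffs[1:].copy()
    out = []
    for m in models:
        c = m.coeffs.copy()
        c[1:] -= ref_rows
        out.append(DCTMovementModel(c, N))
    return out
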