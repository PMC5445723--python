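"""Forward and inverse spatial models for slice-to-volume resampling.

Forward model: given a complete volume on the regular grid and the
movement parameters at each excitation time, predict the slices that the
scanner observed, by sampling the volume with a regular-grid spline at
rigidly transformed coordinates.

Inverse model: the acquired slices are irregularly positioned along the
slice axis.  For every in-plane position (x, y) of the target grid we
solve, per slice s, the closed form for the through-plane coordinate z*
at which that slice's sample actually lies, interpolate the slice in 2D
at the matching in-plane point (x', y'), and collect per-column pairs
(intensity g, coordinate z*).  Each column is then resampled onto the
regular z grid by fitting cubic B-splines in a regularised least-squares
sense; grid points that fall in sampling gaps can be filled by
prediction values entering the fit as weighted pseudo-observations.
A fast piecewise-linear column resampler is used during iterative
parameter estimation.

Conventions: arrays are indexed (x, y, z) with the slice axis last;
rigid transforms act in world mm (see :mod:`s2v.geometry`); spline
coefficients use an extended basis with knots at -1 .. n_grid so edge
grid points are representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import RigidParams, invert_rigid, make_rigid_matrix, voxel_world_maps
from .temporal import DCTMovementModel, SliceTiming

__all__ = [
    "DisplacementField",
    "IrregularColumn",
    "ColumnSet",
    "DegenerateGeometryError",
    "bspline_basis",
    "solve_zstar",
    "predict_observed_slice",
    "forward_model_volume",
    "resample_volume_rigid",
    "build_columns",
    "fit_irregular_spline",
    "evaluate_on_grid",
    "prediction_weights",
    "resample_column_with_predictions",
    "fast_linear_resample",
    "reconstruct_volume",
]

#: threshold on |R^I_33| below which the slice plane is near-parallel to z
EPS_R33 = 1e-6

#: exact-tie tolerance: a z* this close to a grid point counts as an observation
TIE_TOL = 1e-9


class DegenerateGeometryError(RuntimeError):
    """Slice plane nearly parallel to the slice axis; z* is undefined."""


@dataclass(frozen=True)
class DisplacementField:
    """Static per-voxel displacement (mm) along the phase-encode axis.

    Known, externally supplied maps (susceptibility or eddy-current
    induced); never estimated here.  ``axis`` is the in-plane PE voxel
    axis (0 or 1).
    """

    values: np.ndarray
    provenance: str = "susceptibility"
    axis: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field contains non-finite values")
        if self.axis not in (0, 1):
            raise ValueError("PE axis must be in-plane (0 or 1)")
        object.__setattr__(self, "values", v)


@dataclass
class IrregularColumn:
    """Per-(x, y) irregular samples: intensities g at coordinates z*.

    ``zstar`` is in slice-index units of the model space; ``slices``
    records the source slice of each entry.  Entries are sorted by z*.
    """

    g: np.ndarray
    zstar: np.ndarray
    slices: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float).ravel()
        z = np.asarray(self.zstar, dtype=float).ravel()
        s = np.asarray(self.slices, dtype=int).ravel()
        if not (g.size == z.size == s.size):
            raise ValueError("g, zstar and slices must have equal length")
        if not np.all(np.isfinite(z)):
            raise ValueError("z* coordinates must be finite")
        order = np.argsort(z, kind="stable")
        self.g, self.zstar, self.slices = g[order], z[order], s[order]

    def __len__(self) -> int:
        return self.g.size


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _as_time_params(model, timing: SliceTiming) -> np.ndarray:
    """Per-excitation-time (N, 6) parameter array from a model or array."""
    if isinstance(model, DCTMovementModel):
        if model.n_times != timing.n_times:
            raise ValueError(
                f"model has {model.n_times} times, timing {timing.n_times}"
            )
        return model.trace()
    arr = np.asarray(model, dtype=float)
    if arr.shape != (timing.n_times, 6):
        raise ValueError(
            f"expected ({timing.n_times}, 6) parameter array, got {arr.shape}"
        )
    return arr


def _voxel_maps(shape, voxel_size):
    v2w, w2v = voxel_world_maps(shape, voxel_size)
    return v2w, w2v


def _summed_field(fields, shape) -> np.ndarray | None:
    """Sum optional displacement fields into one (nx, ny, nz) mm map per axis."""
    if not fields:
        return None
    out = None
    axis = None
    for f in fields:
        if f.values.shape != tuple(shape):
            raise ValueError(
                f"field shape {f.values.shape} does not match grid {tuple(shape)}"
            )
        if axis is None:
            axis = f.axis
        elif f.axis != axis:
            raise ValueError("all displacement fields must share the PE axis")
        out = f.values if out is None else out + f.values
    return out, axis


def _forward_slice_coords(r: RigidParams, s, shape, voxel_size, fields=None):
    """Model-space voxel sampling coordinates for observation slice ``s``.

    Returns coords (3, nx*ny) and the inside-volume mask.
    """
    nx, ny, nz = shape
    v2w, w2v = _voxel_maps(shape, voxel_size)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.stack(
        [xs.ravel(), ys.ravel(), np.full(nx * ny, float(s))], axis=0
    ).astype(float)
    world = v2w[:3, :3] @ pts + v2w[:3, 3:4]
    if fields is not None:
        d, axis = fields
        disp = ndimage.map_coordinates(d, pts, order=1, mode="nearest")
        world[axis] = world[axis] + disp
    R = make_rigid_matrix(r)
    world = R[:3, :3] @ world + R[:3, 3:4]
    vox = w2v[:3, :3] @ world + w2v[:3, 3:4]
    dims = np.array([nx, ny, nz], dtype=float)
    inside = np.all((vox >= -TIE_TOL) & (vox <= (dims[:, None] - 1) + TIE_TOL), axis=0)
    return vox, inside


def predict_observed_slice(
    fhat: np.ndarray,
    model,
    timing: SliceTiming,
    s: int,
    voxel_size=1.0,
    fields: Sequence[DisplacementField] | None = None,
    order: int = 3,
    prefiltered: bool = False,
):
    """Forward model for one slice: sample ``fhat`` under slice-s movement.

    Returns ``(slice2d, inside2d)`` where ``inside2d`` flags samples
    taken inside the volume; outside samples use constant edge
    extension and should be excluded from estimation costs.
    """
    fhat = np.asarray(fhat, dtype=float)
    params = _as_time_params(model, timing)
    r = RigidParams.from_array(params[timing.time_of_slice(s)])
    fsum = _summed_field(fields, fhat.shape) if fields else None
    vox, inside = _forward_slice_coords(r, s, fhat.shape, voxel_size, fsum)
    vals = ndimage.map_coordinates(
        fhat, vox, order=order, mode="nearest", prefilter=not prefiltered
    )
    nx, ny = fhat.shape[:2]
    return vals.reshape(nx, ny), inside.reshape(nx, ny)


def forward_model_volume(
    fhat: np.ndarray,
    model,
    timing: SliceTiming,
    voxel_size=1.0,
    fields: Sequence[DisplacementField] | None = None,
    order: int = 3,
    prefiltered: bool = False,
):
    """Forward model for all slices at once; returns (volume, inside mask).

    Equivalent to stacking :func:`predict_observed_slice` over s, but
    with a single interpolation call.
    """
    fhat = np.asarray(fhat, dtype=float)
    nx, ny, nz = fhat.shape
    params = _as_time_params(model, timing)
    fsum = _summed_field(fields, fhat.shape) if fields else None
    coords = np.empty((3, nz, nx * ny))
    inside = np.empty((nz, nx * ny), dtype=bool)
    for s in range(nz):
        r = RigidParams.from_array(params[timing.time_of_slice(s)])
        vox, ins = _forward_slice_coords(r, s, fhat.shape, voxel_size, fsum)
        coords[:, s, :] = vox
        inside[s] = ins
    vals = ndimage.map_coordinates(
        fhat,
        coords.reshape(3, -1),
        order=order,
        mode="nearest",
        prefilter=not prefiltered,
    )
    vol = np.moveaxis(vals.reshape(nz, nx, ny), 0, -1)
    ins = np.moveaxis(inside.reshape(nz, nx, ny), 0, -1)
    return vol, ins


def resample_volume_rigid(vol: np.ndarray, r: RigidParams, voxel_size=1.0,
                          order: int = 3) -> np.ndarray:
    """Standard volumetric rigid resampling: out(x) = vol(R x) for all x."""
    vol = np.asarray(vol, dtype=float)
    nx, ny, nz = vol.shape
    v2w, w2v = _voxel_maps(vol.shape, voxel_size)
    R = make_rigid_matrix(r)
    M = w2v @ R @ v2w
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(float)
    vox = M[:3, :3] @ pts + M[:3, 3:4]
    vals = ndimage.map_coordinates(vol, vox, order=order, mode="nearest")
    return vals.reshape(vol.shape)


# ---------------------------------------------------------------------------
# inverse model: z* and column building
# ---------------------------------------------------------------------------

def solve_zstar(x, y, s, Rinv: np.ndarray):
    """Closed-form solution of the slice-plane equation.

    ``Rinv`` is the inverse voxel-space transform for slice ``s`` (the
    matrix mapping model coordinates [x, y, z*, 1] to observation
    coordinates [x', y', s, 1]).  Returns ``(xp, yp, zstar)``; the
    triple satisfies the plane equation to machine precision.
    """
    Rinv = np.asarray(Rinv, dtype=float)
    r33 = Rinv[2, 2]
    if abs(r33) <= EPS_R33:
        raise DegenerateGeometryError(
            f"|R^I_33| = {abs(r33):.2e} <= {EPS_R33}: slice plane nearly "
            "parallel to the slice axis"
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zstar = (s - Rinv[2, 0] * x - Rinv[2, 1] * y - Rinv[2, 3]) / r33
    xp = Rinv[0, 0] * x + Rinv[0, 1] * y + Rinv[0, 2] * zstar + Rinv[0, 3]
    yp = Rinv[1, 0] * x + Rinv[1, 1] * y + Rinv[1, 2] * zstar + Rinv[1, 3]
    return xp, yp, zstar


@dataclass
class ColumnSet:
    """Batched irregular columns for one volume.

    Arrays are (n_slices, nx, ny): ``zstar`` coordinates, ``g``
    intensities, and ``valid`` flags (False where the in-plane point
    fell outside the source slice or the slice was excluded).
    """

    zstar: np.ndarray
    g: np.ndarray
    valid: np.ndarray

    @property
    def n_slices(self) -> int:
        return self.zstar.shape[0]

    def column(self, x: int, y: int) -> IrregularColumn:
        v = self.valid[:, x, y]
        return IrregularColumn(
            self.g[v, x, y], self.zstar[v, x, y], np.flatnonzero(v)
        )


def build_columns(
    observed: np.ndarray,
    model,
    timing: SliceTiming,
    voxel_size=1.0,
    fields: Sequence[DisplacementField] | None = None,
    exclude_slices=None,
) -> ColumnSet:
    """Map every observed slice sample into model space per column.

    For each slice s and regular in-plane (x, y), solve for
    (x', y', z*), interpolate the slice in 2D (cubic spline) at
    (x', y'), and record (g, z*) in column (x, y).  Entries whose
    (x', y') fall outside the slice are flagged invalid, as are entries
    from ``exclude_slices`` (e.g. dropout slices to be replaced by
    predictions).
    """
    observed = np.asarray(observed, dtype=float)
    nx, ny, nz = observed.shape
    if timing.n_slices != nz:
        raise ValueError(f"timing has {timing.n_slices} slices, volume {nz}")
    params = _as_time_params(model, timing)
    v2w, w2v = _voxel_maps(observed.shape, voxel_size)
    fsum = _summed_field(fields, observed.shape) if fields else None
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xf, yf = xs.ravel().astype(float), ys.ravel().astype(float)

    Z = np.empty((nz, nx, ny))
    G = np.empty((nz, nx, ny))
    V = np.ones((nz, nx, ny), dtype=bool)
    excl = set(int(s) for s in exclude_slices) if exclude_slices is not None else set()

    for s in range(nz):
        r = RigidParams.from_array(params[timing.time_of_slice(s)])
        M = w2v @ make_rigid_matrix(r) @ v2w
        try:
            xp, yp, zst = solve_zstar(xf, yf, s, invert_rigid_voxel(M))
        except DegenerateGeometryError as e:
            raise DegenerateGeometryError(f"slice {s}: {e}") from e
        if fsum is not None:
            d, axis = fsum
            # one-step fixed point: the PE displacement shifts the
            # in-plane 2D sampling coordinate of the observed slice
            sample = np.stack([xp, yp, np.full_like(xp, float(s))])
            disp = ndimage.map_coordinates(d, sample, order=1, mode="nearest")
            disp_vox = disp / np.broadcast_to(
                np.asarray(voxel_size, dtype=float), (3,)
            )[axis]
            if axis == 0:
                xp = xp - disp_vox
            else:
                yp = yp - disp_vox
        vals = ndimage.map_coordinates(
            observed[:, :, s], np.stack([xp, yp]), order=3, mode="nearest"
        )
        ok = (
            (xp >= -TIE_TOL)
            & (xp <= nx - 1 + TIE_TOL)
            & (yp >= -TIE_TOL)
            & (yp <= ny - 1 + TIE_TOL)
        )
        Z[s] = zst.reshape(nx, ny)
        G[s] = vals.reshape(nx, ny)
        V[s] = ok.reshape(nx, ny)
        if s in excl:
            V[s] = False
    return ColumnSet(Z, G, V)


def invert_rigid_voxel(M: np.ndarray) -> np.ndarray:
    """Inverse of a voxel-space transform w2v @ R @ v2w (general 4x4)."""
    return np.linalg.inv(M)


# ---------------------------------------------------------------------------
# 1D irregular spline machinery
# ---------------------------------------------------------------------------

def bspline_basis(x):
    """The cubic B-spline kernel: 2/3 - x^2(2-|x|)/2 on |x|<1,
    (2-|x|)^3/6 on 1<=|x|<2, zero otherwise.  Symmetric, support (-2, 2),
    and partition of unity over integer shifts."""
    x = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    inner = x < 1
    outer = (x >= 1) & (x < 2)
    xi = x[inner]
    out[inner] = 2.0 / 3.0 + xi * xi * (xi - 2.0) / 2.0
    xo = x[outer]
    out[outer] = (2.0 - xo) ** 3 / 6.0
    return out if out.ndim else float(out)


def _n_coef(n_grid: int) -> int:
    # extended basis: knots at -1 .. n_grid so edge grid points are representable
    return n_grid + 2


def _design_irregular(zstar: np.ndarray, n_grid: int) -> np.ndarray:
    j = np.arange(_n_coef(n_grid)) - 1.0
    return bspline_basis(np.asarray(zstar, dtype=float)[:, None] - j[None, :])


def _design_regular(n_grid: int) -> np.ndarray:
    i = np.arange(n_grid, dtype=float)
    return _design_irregular(i, n_grid)


def _penalty_D(n_grid: int) -> np.ndarray:
    """Second-difference coefficient penalty; annihilates affine coefficient
    sequences, hence affine interpolants."""
    nc = _n_coef(n_grid)
    P2 = np.zeros((nc - 2, nc))
    idx = np.arange(nc - 2)
    P2[idx, idx] = 1.0
    P2[idx, idx + 1] = -2.0
    P2[idx, idx + 2] = 1.0
    return P2.T @ P2


def _col_arrays(col):
    if isinstance(col, IrregularColumn):
        return col.zstar, col.g
    z, g = col
    z = np.asarray(z, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    order = np.argsort(z, kind="stable")
    return z[order], g[order]


def fit_irregular_spline(col, n_grid: int, lam: float = 0.01) -> np.ndarray:
    """Regularised LSQ cubic-spline fit to irregular samples.

    Solves ``(W^T W + lam D) c = W^T g`` where W has entries
    ``B(z*_i - j)`` over the extended knot range and D penalises second
    differences of the coefficients.  ``col`` is an
    :class:`IrregularColumn` or a ``(zstar, g)`` pair.
    """
    z, g = _col_arrays(col)
    if z.size == 0:
        raise ValueError("cannot fit a spline to an empty column")
    W = _design_irregular(z, n_grid)
    A = W.T @ W + lam * _penalty_D(n_grid)
    b = W.T @ g
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular spline normal matrix (empty support region); "
            "use lam > 0 or supply predictions"
        ) from e
    if not np.all(np.isfinite(c)):
        raise np.linalg.LinAlgError(
            "non-finite spline solution; use lam > 0 or supply predictions"
        )
    return c


def evaluate_on_grid(c_hat: np.ndarray, n_grid: int) -> np.ndarray:
    """Spline values on the regular grid: ``W(r) c`` with W(r)_ij = B(i-j)."""
    c_hat = np.asarray(c_hat, dtype=float)
    if c_hat.shape[-1] != _n_coef(n_grid):
        raise ValueError(
            f"expected {_n_coef(n_grid)} coefficients, got {c_hat.shape[-1]}"
        )
    return c_hat @ _design_regular(n_grid).T


def prediction_weights(zstar, n_grid: int) -> np.ndarray:
    """Per-grid-point weights for prediction pseudo-observations.

    Observations always take precedence: a grid point tightly bracketed
    by observations gets weight 0 and the total prediction weight in a
    bracket of width 1 < dz <= 3 is dz - 1.  Grid points outside the
    outermost observations get weight 1 (pure prediction); a z* landing
    exactly on a grid point counts as an observation there.
    """
    zs = np.sort(np.asarray(zstar, dtype=float).ravel())
    if zs.size == 0:
        return np.ones(n_grid)
    i = np.arange(n_grid, dtype=float)
    hi_idx = np.searchsorted(zs, i)
    interior = (hi_idx > 0) & (hi_idx < zs.size)
    hi_safe = np.clip(hi_idx, 1, zs.size - 1)
    lo = zs[hi_safe - 1]
    hi = zs[hi_safe]
    dz = hi - lo
    m = np.floor(hi - TIE_TOL) - np.ceil(lo + TIE_TOL) + 1
    dp = np.minimum(i - lo, hi - i)
    w = np.select(
        [m <= 1, m == 2],
        [dz - 1.0, dp],
        default=np.minimum(dp, 1.0),
    )
    w = np.where(dz <= 1.0, 0.0, w)
    w = np.where(interior, w, 1.0)          # outside: pure prediction
    tie = np.abs(zs[np.minimum(hi_idx, zs.size - 1)] - i) <= TIE_TOL
    tie |= np.abs(lo - i) <= TIE_TOL
    w = np.where(tie, 0.0, w)
    return np.clip(w, 0.0, 1.0)


def observation_density(zstar, n_grid: int) -> np.ndarray:
    """Local observation spacing per grid point (QC map).

    The width of the bracketing observation pair, 0 at an exact tie and
    +inf outside the outermost observations.
    """
    zs = np.sort(np.asarray(zstar, dtype=float).ravel())
    if zs.size == 0:
        return np.full(n_grid, np.inf)
    i = np.arange(n_grid, dtype=float)
    hi_idx = np.searchsorted(zs, i)
    interior = (hi_idx > 0) & (hi_idx < zs.size)
    hi_safe = np.clip(hi_idx, 1, zs.size - 1)
    out = np.where(interior, zs[hi_safe] - zs[hi_safe - 1], np.inf)
    tie = np.abs(zs[np.minimum(hi_idx, zs.size - 1)] - i) <= TIE_TOL
    tie |= np.abs(zs[hi_safe - 1] - i) <= TIE_TOL
    return np.where(tie, 0.0, out)


def resample_column_with_predictions(col, p, w, lam: float = 0.01) -> np.ndarray:
    """Weighted LSQ column resampling mixing observations and predictions.

    Stacks the irregular design on the observations with the regular
    design weighted by ``w`` on the predictions ``p`` and solves the
    normal equations.  With w = 0 everywhere this reduces to
    :func:`fit_irregular_spline` + :func:`evaluate_on_grid`; where
    observations are absent and w = 1 the result follows p.
    """
    z, g = _col_arrays(col)
    p = np.asarray(p, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    n_grid = p.size
    if w.size != n_grid:
        raise ValueError("p and w must have equal length")
    Wr = _design_regular(n_grid)
    Wi = _design_irregular(z, n_grid) if z.size else np.zeros((0, _n_coef(n_grid)))
    A = Wi.T @ Wi + (Wr * (w**2)[:, None]).T @ Wr + lam * _penalty_D(n_grid)
    b = (Wi.T @ g if z.size else 0.0) + Wr.T @ (w**2 * p)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular weighted system; ensure some weight covers every gap"
        ) from e
    return Wr @ c


def fast_linear_resample(col, n_grid: int) -> np.ndarray:
    """Piecewise-linear column resampling used during estimation.

    Linear interpolation of (z*, g) at the integer grid points with
    constant extrapolation beyond the outermost samples; no predictions
    are used.
    """
    z, g = _col_arrays(col)
    if z.size < 2:
        raise ValueError(f"need >= 2 samples for linear resampling, got {z.size}")
    return np.interp(np.arange(n_grid, dtype=float), z, g)


# ---------------------------------------------------------------------------
# whole-volume reconstruction
# ---------------------------------------------------------------------------

def reconstruct_volume(
    observed: np.ndarray,
    model,
    timing: SliceTiming,
    prediction: np.ndarray | None = None,
    lam: float = 0.01,
    mode: str = "spline",
    voxel_size=1.0,
    fields: Sequence[DisplacementField] | None = None,
    exclude_slices=None,
    with_density: bool = True,
):
    """Resample one observed volume onto the regular grid.

    2D spline interpolation per slice followed by per-column 1D
    irregular resampling: cubic-spline with prediction-weighted gap
    filling (``mode='spline'``) for final output, or piecewise linear
    (``mode='fast'``) during estimation.  Returns ``(volume, density)``
    where density is the local observation-spacing QC map.
    """
    observed = np.asarray(observed, dtype=float)
    nx, ny, nz = observed.shape
    cs = build_columns(
        observed, model, timing, voxel_size, fields, exclude_slices
    )
    out = np.empty_like(observed)
    dens = np.empty_like(observed) if with_density else None
    if mode == "fast":
        grid = np.arange(nz, dtype=float)
        for x in range(nx):
            for y in range(ny):
                v = cs.valid[:, x, y]
                z = cs.zstar[v, x, y]
                g = cs.g[v, x, y]
                order = np.argsort(z, kind="stable")
                z, g = z[order], g[order]
                if z.size >= 2:
                    out[x, y] = np.interp(grid, z, g)
                elif z.size == 1:
                    out[x, y] = g[0]
                elif prediction is not None:
                    out[x, y] = prediction[x, y]
                else:
                    out[x, y] = 0.0
                if with_density:
                    dens[x, y] = observation_density(z, nz)
        return out, dens
    if mode != "spline":
        raise ValueError(f"unknown reconstruction mode {mode!r}")

    ncoef = _n_coef(nz)
    Wr = _design_regular(nz)
    D = _penalty_D(nz)
    # batched design: rows for invalid entries are zeroed, which removes
    # them from the least-squares problem
    Zt = np.moveaxis(cs.zstar, 0, -1).reshape(-1, nz)      # (ncol, ns)
    Gt = np.moveaxis(cs.g, 0, -1).reshape(-1, nz)
    Vt = np.moveaxis(cs.valid, 0, -1).reshape(-1, nz)
    j = np.arange(ncoef) - 1.0
    T = bspline_basis(Zt[:, :, None] - j[None, None, :])
    T *= Vt[:, :, None]
    A = np.einsum("csk,csl->ckl", T, T, optimize=True)
    b = np.einsum("csk,cs->ck", T, Gt * Vt, optimize=True)
    A += lam * D[None, :, :]

    W = np.zeros((Zt.shape[0], nz))
    dens_flat = np.empty((Zt.shape[0], nz)) if with_density else None
    for c in range(Zt.shape[0]):
        z = np.sort(Zt[c][Vt[c]])
        if with_density:
            dens_flat[c] = observation_density(z, nz)
        if prediction is not None:
            W[c] = prediction_weights(z, nz)
    if prediction is not None:
        P = np.asarray(prediction, dtype=float).reshape(-1, nz)
        A += np.einsum("ik,ci,il->ckl", Wr, W**2, Wr, optimize=True)
        b += np.einsum("ik,ci->ck", Wr, W**2 * P, optimize=True)

    # columns with nothing to constrain them (no samples, no weights)
    n_valid = Vt.sum(axis=1)
    blind = (n_valid == 0) & (
        (W.sum(axis=1) == 0) if prediction is not None else True
    )
    if np.any(blind):
        A[blind] = np.eye(ncoef)[None]
        b[blind] = 0.0
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    y = coef @ Wr.T
    if prediction is not None and np.any(blind):
        y[blind] = np.asarray(prediction, dtype=float).reshape(-1, nz)[blind]
    out = y.reshape(nx, ny, nz)
    dens = dens_flat.reshape(nx, ny, nz) if with_density else None
    return out, dens
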