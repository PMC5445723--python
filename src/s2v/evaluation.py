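"""Quantitative assessment: slice-wise registration error, tensor/FA fits
and FA fidelity.

Registration error follows the vertical-distance convention: for every
slice (restricted to slices with an appreciable amount of brain) the
error of a movement parameter is the difference between the estimated
and the true value at that slice's excitation time, and a volume's RMSE
is the root mean square over its included slices.  Volumetric
(volume-to-volume) estimates enter as constants across a volume's
slices.  Summary numbers average the per-volume RMSEs over the three
translation axes / three rotation axes and over volumes; rotations are
reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import DiffusionScheme
from .temporal import SliceTiming

__all__ = [
    "RegistrationErrorReport",
    "per_volume_rmse",
    "wls_tensor_fit",
    "fa_from_tensors",
    "fa_fidelity",
]


@dataclass
class RegistrationErrorReport:
    """Per-volume, per-parameter slice-wise RMSE and its aggregates.

    ``rmse`` is (n_vols, 6) in mm (columns 0-2) and degrees (3-5).
    ``translation_mm`` / ``rotation_deg`` average over axes and volumes
    (mean of per-volume RMSEs); the ``pooled_*`` variants pool all
    squared errors before the root, the alternative aggregation order.
    """

    rmse: np.ndarray
    translation_mm: float
    rotation_deg: float
    pooled_translation_mm: float
    pooled_rotation_deg: float
    included_slices: np.ndarray

    def by_group(self, scheme: DiffusionScheme) -> dict:
        """Aggregates split by image type (b=0 vs each shell)."""
        out = {}
        for bval, idx in scheme.shells().items():
            sub = self.rmse[idx]
            out[bval] = {
                "translation_mm": float(sub[:, :3].mean()),
                "rotation_deg": float(sub[:, 3:].mean()),
            }
        return out


def per_volume_rmse(
    true_trace: np.ndarray,
    est_trace: np.ndarray,
    timing: SliceTiming,
    included_slices=None,
) -> RegistrationErrorReport:
    """Slice-wise RMSE of estimated movement against the true trace.

    Traces are (n_vols, N, 6) on the same excitation grid, translations
    in mm and rotations in radians; the report converts rotations to
    degrees.  ``included_slices`` is a boolean mask over slice indices
    (slices with enough brain); it must select at least one slice.
    """
    true_trace = np.asarray(true_trace, dtype=float)
    est_trace = np.asarray(est_trace, dtype=float)
    if true_trace.shape != est_trace.shape:
        raise ValueError(
            f"trace shapes differ: {true_trace.shape} vs {est_trace.shape}"
        )
    n_vols, N, _ = true_trace.shape
    if N != timing.n_times:
        raise ValueError("traces are not on the timing's excitation grid")
    if included_slices is None:
        included_slices = np.ones(timing.n_slices, dtype=bool)
    included_slices = np.asarray(included_slices, dtype=bool)
    slice_idx = np.flatnonzero(included_slices)
    if slice_idx.size == 0:
        raise ValueError("included slice set is empty")
    times = timing.slice_to_time[slice_idx]

    err = est_trace[:, times, :] - true_trace[:, times, :]  # (n_vols, n_inc, 6)
    err = err.copy()
    err[:, :, 3:] = np.rad2deg(err[:, :, 3:])
    rmse = np.sqrt(np.mean(err**2, axis=1))
    return RegistrationErrorReport(
        rmse=rmse,
        translation_mm=float(rmse[:, :3].mean()),
        rotation_deg=float(rmse[:, 3:].mean()),
        pooled_translation_mm=float(np.sqrt(np.mean(err[:, :, :3] ** 2))),
        pooled_rotation_deg=float(np.sqrt(np.mean(err[:, :, 3:] ** 2))),
        included_slices=included_slices,
    )


# ---------------------------------------------------------------------------
# tensor fitting
# ---------------------------------------------------------------------------

def _design(scheme: DiffusionScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def wls_tensor_fit(series: np.ndarray, scheme: DiffusionScheme, mask: np.ndarray):
    """Weighted least-squares diffusion tensor fit of log-transformed data.

    Per voxel solves ``log S = log S0 - b g^T D g`` with weights equal to
    the squared signals predicted by a first-pass OLS fit; non-positive
    signals are clamped at a small floor before the log.  Returns
    ``(tensors, fa)`` with tensors of shape mask-voxels x 3 x 3 mapped
    back onto the grid (zeros outside the mask).
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    X = _design(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise np.linalg.LinAlgError(
            "rank-deficient tensor design: need b=0 plus >= 6 unique directions"
        )
    S = np.moveaxis(series, 0, -1)[mask]  # (nvox, n_vols)
    floor = 1e-6 * float(series.max())
    S = np.maximum(S, floor)
    y = np.log(S)

    # first pass: OLS
    beta0, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, nvox)
    w = np.exp(2.0 * (X @ beta0)).T  # predicted squared signals, (nvox, n_vols)

    XtW = X.T[None, :, :] * w[:, None, :]             # (nvox, 7, n_vols)
    A = XtW @ X[None, :, :]
    rhs = np.einsum("vkn,vn->vk", XtW, y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]  # (nvox, 7)

    tensors = np.zeros(mask.shape + (3, 3))
    Dv = np.empty((beta.shape[0], 3, 3))
    Dv[:, 0, 0] = beta[:, 1]
    Dv[:, 1, 1] = beta[:, 2]
    Dv[:, 2, 2] = beta[:, 3]
    Dv[:, 0, 1] = Dv[:, 1, 0] = beta[:, 4]
    Dv[:, 0, 2] = Dv[:, 2, 0] = beta[:, 5]
    Dv[:, 1, 2] = Dv[:, 2, 1] = beta[:, 6]
    tensors[mask] = Dv
    fa = np.zeros(mask.shape)
    fa[mask] = fa_from_tensors(Dv)
    return tensors, fa


def fa_from_tensors(tensors: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from tensor eigenvalue dispersion."""
    ev = np.linalg.eigvalsh(np.asarray(tensors, dtype=float))
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5 * ((ev - md) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_fidelity(
    corrected: np.ndarray,
    truth_fa: np.ndarray,
    mask: np.ndarray,
    scheme: DiffusionScheme,
) -> float:
    """Pearson correlation between estimated and true FA over brain voxels.

    The mask is eroded by one voxel first so only interior voxels enter.
    """
    from scipy import ndimage

    mask = ndimage.binary_erosion(np.asarray(mask, dtype=bool))
    if not np.any(mask):
        raise ValueError("mask empty after one-voxel erosion")
    _, fa = wls_tensor_fit(corrected, scheme, mask)
    a = fa[mask]
    b = np.asarray(truth_fa, dtype=float)[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("FA constant within the mask; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
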