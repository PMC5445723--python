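"""Per-volume estimation of DCT movement coefficients and the full
iterative slice-to-volume correction algorithm.

Each outer iteration: (1) resample every volume onto the regular grid
at the current movement estimates (fast linear column interpolation),
(2) refit the q-space predictor on the resampled volumes, (3) update
each volume's DCT coefficients by regularised Gauss-Newton steps
against the forward-model projection of its prediction, (4) pick a
shape-reference volume (separately for b=0 and diffusion-weighted
volumes) among those least affected by intra-volume movement and
regress its non-constant terms out of all volumes, then anchor the
output space by subtracting the first b=0 volume's constant position
from every volume.  After convergence the series is
reconstructed once in high-fidelity spline mode with
prediction-weighted gap filling; dropout-flagged slices are excluded
from both the cost and the final columns, so predictions replace them.

Cost scaling: the data term is the sum of squared residuals over
usable in-brain voxels divided by the sum of squared observed
intensities over the same (parameter-independent) voxel set, and the
movement penalty is the mean squared second temporal derivative with
rotations counted in degrees.  This makes the regularisation weight
``lam`` dimensionless with a useful range of roughly 0.1 - 100
regardless of scanner intensity scaling or grid size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .predictor import PredictorConfig, fit_predictor
from .resampling import forward_model_volume, reconstruct_volume
from .scheme import DiffusionScheme
from .temporal import (
    DCTMovementModel,
    SliceTiming,
    apply_shape_reference,
    dct_design_matrix,
    penalty_matrix,
)

__all__ = [
    "EstimationConfig",
    "CorrectionResult",
    "brain_mask",
    "included_slice_mask",
    "volume_cost",
    "gauss_newton_step",
    "run_correction",
]

log = logging.getLogger(__name__)

#: per-parameter units used in the movement penalty: mm and degrees
_PEN_UNITS = np.array([1.0, 1.0, 1.0] + [np.rad2deg(1.0)] * 3)

#: calibration constant of the penalty scale: with it, lam = 1 is a mild
#: constraint at typical b=0 SNR (penalty well below the noise floor of the
#: data term) and lam = 100 smooths strongly, centring the useful range of
#: lam on roughly 0.1 - 100.
_PEN_SCALE = 0.05


@dataclass
class EstimationConfig:
    """Tuning knobs of the slice-to-volume estimator.

    ``dof`` is the number of DCT basis functions per movement parameter
    (M + 1; 1 reproduces volume-to-volume registration).  ``lam`` is the
    temporal regularisation weight (dimensionless, useful range
    0.1 - 100).  Finite-difference steps are 0.2 mm / 0.2 degrees.
    """

    dof: int = 8
    lam: float = 1.0
    max_outer: int = 4
    volumetric_iters: int = 2
    gn_iters: int = 2
    tol: float = 1e-4
    step_mm: float = 0.2
    step_deg: float = 0.2
    use_dropout_mask: bool = True
    slice_min_frac: float = 0.02
    spline_lam: float = 1e-4
    max_halvings: int = 6
    est_smooth_vox: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.step_mm <= 0 or self.step_deg <= 0:
            raise ValueError("finite-difference steps must be positive")

    @property
    def fd_steps(self) -> np.ndarray:
        return np.array(
            [self.step_mm] * 3 + [np.deg2rad(self.step_deg)] * 3
        )


@dataclass
class CorrectionResult:
    """Everything the correction run produced."""

    models: list
    motion: np.ndarray            # (n_vols, N, 6) mm / radians
    corrected: np.ndarray         # 4D series on the regular grid
    log: list = field(default_factory=list)
    converged: bool = True
    shape_ref: dict = field(default_factory=dict)
    mask: np.ndarray | None = None
    included_slices: np.ndarray | None = None
    density: np.ndarray | None = None

    def motion_table(self, timing: SliceTiming):
        """Per-excitation motion table (degrees for rotations)."""
        import pandas as pd

        rows = []
        for i in range(self.motion.shape[0]):
            for n in range(self.motion.shape[1]):
                p = self.motion[i, n]
                rows.append(
                    {
                        "volume": i,
                        "time": n,
                        "slices": ",".join(str(s) for s in timing.groups[n]),
                        "dx_mm": p[0],
                        "dy_mm": p[1],
                        "dz_mm": p[2],
                        "rx_deg": np.rad2deg(p[3]),
                        "ry_deg": np.rad2deg(p[4]),
                        "rz_deg": np.rad2deg(p[5]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def brain_mask(series: np.ndarray, scheme: DiffusionScheme) -> np.ndarray:
    """Otsu threshold on the mean b=0 volume, eroded by one voxel."""
    series = np.asarray(series, dtype=float)
    mean_b0 = series[scheme.is_b0].mean(axis=0)
    thr = threshold_otsu(mean_b0)
    mask = mean_b0 > thr
    return ndimage.binary_erosion(mask)


def included_slice_mask(mask: np.ndarray, min_frac: float = 0.02) -> np.ndarray:
    """Slices with an appreciable amount of brain (>= min_frac in-plane)."""
    nx, ny, _ = mask.shape
    counts = mask.sum(axis=(0, 1))
    return counts >= min_frac * nx * ny


# ---------------------------------------------------------------------------
# cost and Gauss-Newton
# ---------------------------------------------------------------------------

def _usable(mask, inside, included_slices, dropout_slices):
    use = mask & inside
    keep = np.array(included_slices, dtype=bool).copy()
    if dropout_slices is not None:
        keep &= ~np.asarray(dropout_slices, dtype=bool)
    use &= keep[None, None, :]
    return use


def _static_voxels(mask, included_slices, dropout_slices):
    keep = np.array(included_slices, dtype=bool).copy()
    if dropout_slices is not None:
        keep &= ~np.asarray(dropout_slices, dtype=bool)
    return mask & keep[None, None, :]


def _penalty_quadform(N: int, M: int, scale: np.ndarray | None = None):
    """Block-diagonal penalty over vec(B) in parameter-major order."""
    P = penalty_matrix(N, M) * (_PEN_SCALE / N)
    d = 6 * (M + 1)
    Q = np.zeros((d, d))
    units = _PEN_UNITS if scale is None else scale
    for p in range(6):
        sl = slice(p * (M + 1), (p + 1) * (M + 1))
        Q[sl, sl] = units[p] ** 2 * P
    return Q


def _scaled_penalty(model: DCTMovementModel) -> float:
    Q = _penalty_quadform(model.n_times, model.order)
    b = model.coeffs.T.reshape(-1)  # parameter-major
    return float(b @ Q @ b)


class _MaskedSampler:
    """Forward-model sampling restricted to usable voxels.

    Estimation only ever compares intensities at in-mask voxels of
    included, non-dropout slices, so the Jacobian and line-search costs
    sample just those points (one interpolation call per evaluation).
    """

    def __init__(self, observed, mask, included_slices, dropout_slices,
                 timing, voxel_size):
        from .geometry import voxel_world_maps

        observed = np.asarray(observed, dtype=float)
        static = _static_voxels(mask, included_slices, dropout_slices)
        nx, ny, nz = observed.shape
        self.shape = observed.shape
        self.timing = timing
        v2w, w2v = voxel_world_maps(observed.shape, voxel_size)
        self._v2w, self._w2v = v2w, w2v
        xs, ys, ss, obs = [], [], [], []
        bounds = [0]
        self.slice_ids = []
        for s in range(nz):
            ix, iy = np.nonzero(static[:, :, s])
            if ix.size == 0:
                continue
            xs.append(ix)
            ys.append(iy)
            ss.append(np.full(ix.size, s))
            obs.append(observed[ix, iy, s])
            bounds.append(bounds[-1] + ix.size)
            self.slice_ids.append(s)
        if not xs:
            raise ValueError("no usable voxels: mask/slice selection is empty")
        vox = np.stack([np.concatenate(a) for a in (xs, ys, ss)]).astype(float)
        self.world = v2w[:3, :3] @ vox + v2w[:3, 3:4]
        self.obs = np.concatenate(obs)
        self.denom = float(np.sum(self.obs**2))
        self.bounds = np.array(bounds)

    def sample(self, fpre, params):
        """Sampled forward-model values and inside flags at the points."""
        from .geometry import RigidParams, make_rigid_matrix

        coords = np.empty_like(self.world)
        t_of = self.timing.slice_to_time
        for k, s in enumerate(self.slice_ids):
            seg = slice(self.bounds[k], self.bounds[k + 1])
            R = make_rigid_matrix(RigidParams.from_array(params[t_of[s]]))
            coords[:, seg] = R[:3, :3] @ self.world[:, seg] + R[:3, 3:4]
        coords = self._w2v[:3, :3] @ coords + self._w2v[:3, 3:4]
        vals = ndimage.map_coordinates(
            fpre, coords, order=3, mode="nearest", prefilter=False
        )
        dims = np.array(self.shape, dtype=float)
        inside = np.all(
            (coords >= -1e-9) & (coords <= dims[:, None] - 1 + 1e-9), axis=0
        )
        return vals, inside

    def data_cost(self, fpre, params):
        vals, inside = self.sample(fpre, params)
        resid = np.where(inside, vals - self.obs, 0.0)
        return float(np.sum(resid**2)) / self.denom


def volume_cost(
    observed: np.ndarray,
    fhat: np.ndarray,
    model: DCTMovementModel,
    timing: SliceTiming,
    lam: float,
    mask: np.ndarray,
    included_slices=None,
    dropout_slices=None,
    voxel_size=1.0,
    order: int = 3,
    return_parts: bool = False,
    prefiltered: bool = False,
):
    """Normalised SSD between observed and forward-projected slices plus
    the weighted movement penalty.  See the module docstring for the
    scaling convention."""
    observed = np.asarray(observed, dtype=float)
    if included_slices is None:
        included_slices = np.ones(observed.shape[2], dtype=bool)
    fwd, inside = forward_model_volume(
        fhat, model, timing, voxel_size=voxel_size, order=order,
        prefiltered=prefiltered,
    )
    use = _usable(mask, inside, included_slices, dropout_slices)
    if not np.any(use):
        raise ValueError("no usable voxels: mask/slice selection is empty")
    denom = float(np.sum(observed[_static_voxels(mask, included_slices, dropout_slices)] ** 2))
    data = float(np.sum((fwd[use] - observed[use]) ** 2)) / denom
    pen = _scaled_penalty(model)
    cost = data + lam * pen
    if return_parts:
        return cost, data, pen
    return cost


def gauss_newton_step(
    observed: np.ndarray,
    fhat: np.ndarray,
    model: DCTMovementModel,
    timing: SliceTiming,
    lam: float,
    cfg: EstimationConfig,
    mask: np.ndarray,
    included_slices=None,
    dropout_slices=None,
    voxel_size=1.0,
):
    """One regularised Gauss-Newton update of a volume's coefficients.

    The residual Jacobian with respect to the six per-time rigid
    parameters is built by central finite differences on the forward
    model (one simultaneous perturbation per parameter), then mapped to
    DCT-coefficient space through the (exact) chain rule; the update
    solves the regularised normal equations with a halving line search
    that only ever accepts non-increasing cost.  Returns
    ``(new_model, info)``.
    """
    observed = np.asarray(observed, dtype=float)
    N, M = model.n_times, model.order
    if included_slices is None:
        included_slices = np.ones(observed.shape[2], dtype=bool)
    params = model.trace()
    steps = cfg.fd_steps
    # cubic forward model throughout; prefilter the prediction once and
    # sample only the usable voxels
    fpre = ndimage.spline_filter(np.asarray(fhat, dtype=float), order=3,
                                 mode="nearest")
    sampler = _MaskedSampler(
        observed, mask, included_slices, dropout_slices, timing, voxel_size
    )
    vals, inside = sampler.sample(fpre, params)
    denom = sampler.denom
    resid = np.where(inside, vals - sampler.obs, 0.0)

    derivs = np.empty((6, resid.size))
    for p in range(6):
        plus = params.copy()
        plus[:, p] += steps[p]
        minus = params.copy()
        minus[:, p] -= steps[p]
        vp, _ = sampler.sample(fpre, plus)
        vm, _ = sampler.sample(fpre, minus)
        derivs[p] = np.where(inside, (vp - vm) / (2.0 * steps[p]), 0.0)

    # per-excitation-time 6x6 Gram blocks and gradient entries
    G = np.zeros((N, 6, 6))
    g = np.zeros((N, 6))
    t_of = timing.slice_to_time
    for k, s in enumerate(sampler.slice_ids):
        seg = slice(sampler.bounds[k], sampler.bounds[k + 1])
        D = derivs[:, seg]
        G[t_of[s]] += D @ D.T
        g[t_of[s]] += D @ resid[seg]

    C = dct_design_matrix(N, M)
    JtJ = np.einsum("nk,nl,npq->pkql", C, C, G).reshape(6 * (M + 1), 6 * (M + 1))
    Jtr = np.einsum("nk,np->pk", C, g).reshape(-1)
    Q = _penalty_quadform(N, M)
    b = model.coeffs.T.reshape(-1)

    A = JtJ / denom + lam * Q
    rhs = -(Jtr / denom + lam * (Q @ b))
    cond = np.linalg.cond(A)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"normal-matrix condition number {cond:.2e} > 1e12; "
            "increase the movement regularisation lam"
        )
    delta = np.linalg.solve(A, rhs)

    cost0 = sampler.data_cost(fpre, params) + lam * _scaled_penalty(model)
    alpha = 1.0
    best = model
    best_cost = cost0
    n_half = 0
    for _ in range(cfg.max_halvings + 1):
        cand = DCTMovementModel(
            model.coeffs + alpha * delta.reshape(6, M + 1).T, N
        )
        cost = sampler.data_cost(fpre, cand.trace()) + lam * _scaled_penalty(cand)
        if cost <= best_cost:
            best, best_cost = cand, cost
            break
        alpha *= 0.5
        n_half += 1
    info = {
        "cost0": cost0,
        "cost": best_cost,
        "step_norm": float(np.linalg.norm(alpha * delta)) if best is not model else 0.0,
        "halvings": n_half,
        "accepted": best is not model,
    }
    return best, info


# ---------------------------------------------------------------------------
# the full algorithm
# ---------------------------------------------------------------------------

def _movement_stat(model: DCTMovementModel) -> float:
    """Within-volume SD of the rotation parameters, averaged over axes
    (degrees) - the intra-volume movement summary."""
    tr = model.trace()
    return float(np.mean(np.std(np.rad2deg(tr[:, 3:]), axis=0)))


def _pick_reference(indices, stats, resids) -> int:
    """Lowest prediction residual among the low-intra-volume-movement half."""
    indices = np.asarray(indices)
    stats = np.asarray(stats)
    resids = np.asarray(resids)
    cand = stats <= np.median(stats)
    sub = indices[cand]
    return int(sub[np.argmin(resids[cand])])


def _reconstruct_all(series, models, timing, voxel_size, exclude, mode="fast",
                     predictions=None, lam=0.01):
    out = np.empty_like(series)
    for i in range(series.shape[0]):
        excl = np.flatnonzero(exclude[i]) if exclude is not None else None
        if (
            mode == "fast"
            and (excl is None or excl.size == 0)
            and not np.any(models[i].coeffs)
        ):
            out[i] = series[i]
            continue
        pred = predictions[i] if predictions is not None else None
        out[i], _ = reconstruct_volume(
            series[i], models[i], timing, prediction=pred, lam=lam,
            mode=mode, voxel_size=voxel_size, exclude_slices=excl,
            with_density=False,
        )
    return out


def run_correction(
    series: np.ndarray,
    scheme: DiffusionScheme,
    timing: SliceTiming,
    cfg: EstimationConfig | None = None,
    voxel_size=1.0,
    dropout_mask: np.ndarray | None = None,
    predictor_config: PredictorConfig | None = None,
) -> CorrectionResult:
    """Estimate intra-volume movement for every volume and correct the series.

    ``series``: 4D array (volume index first, slice axis last);
    ``dropout_mask``: optional (n_vols, n_slices) boolean flagging
    dropout slices to exclude from estimation and replace by
    predictions in the output.
    """
    cfg = cfg or EstimationConfig()
    series = np.asarray(series, dtype=float)
    n_vols = series.shape[0]
    if n_vols != scheme.n_volumes:
        raise ValueError("series and scheme volume counts differ")
    b0_idx = np.flatnonzero(scheme.is_b0)
    dwi_idx = np.flatnonzero(~scheme.is_b0)
    if b0_idx.size < 2:
        raise ValueError("need >= 2 b=0 volumes")
    for bval, idx in scheme.shells().items():
        if bval > 0 and idx.size < 6:
            raise ValueError(
                f"shell b={bval:.0f} has {idx.size} volumes; need >= 6"
            )

    mask = brain_mask(series, scheme)
    included = included_slice_mask(mask, cfg.slice_min_frac)
    dmask = dropout_mask if (dropout_mask is not None and cfg.use_dropout_mask) else None

    M = cfg.dof - 1
    N = timing.n_times
    models = [DCTMovementModel.zeros(M, N) for _ in range(n_vols)]
    run_log = []
    converged = False
    prev_cost = np.inf
    shape_ref: dict = {}

    # estimation operates on mildly smoothed data (observation and target
    # alike) to suppress noise-driven parameter error
    if cfg.est_smooth_vox > 0:
        obs_est = np.stack(
            [ndimage.gaussian_filter(v, cfg.est_smooth_vox) for v in series]
        )
    else:
        obs_est = series

    # warm start: a few volume-to-volume iterations (constant model only)
    # give the predictor roughly aligned training data before the
    # intra-volume terms are released
    n_warm = cfg.volumetric_iters if M > 0 else 0
    predictions = None
    for it in range(-n_warm, cfg.max_outer):
        warm = it < 0
        if predictions is None:
            aligned = _reconstruct_all(series, models, timing, voxel_size, dmask)
        else:
            # once predictions exist, train the predictor on the
            # high-fidelity reconstruction with prediction-filled gaps
            aligned = _reconstruct_all(
                series, models, timing, voxel_size, dmask,
                mode="spline", predictions=predictions, lam=cfg.spline_lam,
            )
        pm = fit_predictor(aligned, scheme, predictor_config)
        predictions = np.stack(
            [pm.predict_index(i) for i in range(n_vols)]
        )
        total = 0.0
        for i in range(n_vols):
            fhat = pm.predict_loo(i)
            drop_i = dmask[i] if dmask is not None else None
            if cfg.est_smooth_vox > 0:
                fhat = ndimage.gaussian_filter(fhat, cfg.est_smooth_vox)
            if warm:
                # constant-only update of this volume's position
                m = DCTMovementModel(models[i].coeffs[:1].copy(), N)
            else:
                m = models[i]
            for _ in range(cfg.gn_iters):
                m, info = gauss_newton_step(
                    obs_est[i], fhat, m, timing, cfg.lam, cfg, mask,
                    included, drop_i, voxel_size,
                )
                if not info["accepted"] or info["step_norm"] < 1e-6:
                    break
            if warm:
                models[i].coeffs[0] = m.coeffs[0]
            else:
                models[i] = m
            total += info["cost"]

        # shape reference per group, then anchor to the b=0 reference
        stats = np.array([_movement_stat(m) for m in models])
        resids = np.array(
            [pm.residual_mss(aligned, i, mask) for i in range(n_vols)]
        )
        ref_b0 = _pick_reference(b0_idx, stats[b0_idx], resids[b0_idx])
        shape_ref = {"b0": ref_b0}
        if M > 0:
            b0_models = apply_shape_reference(
                [models[i] for i in b0_idx], list(b0_idx).index(ref_b0)
            )
            for j, i in enumerate(b0_idx):
                models[i] = b0_models[j]
            if dwi_idx.size:
                ref_dwi = _pick_reference(dwi_idx, stats[dwi_idx], resids[dwi_idx])
                shape_ref["dwi"] = ref_dwi
                dwi_models = apply_shape_reference(
                    [models[i] for i in dwi_idx], list(dwi_idx).index(ref_dwi)
                )
                for j, i in enumerate(dwi_idx):
                    models[i] = dwi_models[j]
        # the first b=0 volume defines the output space: its constant
        # position is subtracted from every volume
        anchor = models[b0_idx[0]].coeffs[0].copy()
        for m in models:
            m.coeffs[0] -= anchor

        run_log.append({"iteration": it, "cost": total})
        log.info("outer iteration %d: total cost %.6g", it, total)
        rel = (prev_cost - total) / max(abs(prev_cost), 1e-30)
        if it > 0 and 0 <= rel < cfg.tol:
            converged = True
            break
        prev_cost = total

    if not converged:
        log.warning("correction did not converge in %d iterations", cfg.max_outer)

    # final high-fidelity reconstruction with prediction-filled gaps
    aligned = _reconstruct_all(series, models, timing, voxel_size, dmask)
    pm = fit_predictor(aligned, scheme, predictor_config)
    predictions = np.stack([pm.predict_index(i) for i in range(n_vols)])
    corrected = _reconstruct_all(
        series, models, timing, voxel_size, dmask,
        mode="spline", predictions=predictions, lam=cfg.spline_lam,
    )
    motion = np.stack([m.trace() for m in models])
    return CorrectionResult(
        models=models,
        motion=motion,
        corrected=corrected,
        log=run_log,
        converged=converged,
        shape_ref=shape_ref,
        mask=mask,
        included_slices=included,
    )
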