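"""Q-space signal predictor ("prediction maker").

Given the set of acquired volume / diffusion-descriptor pairs, the
predictor returns a complete volume on the regular grid for *any*
diffusion descriptor.  It is the registration target of the
slice-to-volume estimator: observed slices are compared with the
forward-model projection of these predictions.

The model is a Gaussian-process regression per shell with a minimal
covariance family built on the angular distance theta = arccos(|g . g'|)
between gradient directions (the absolute dot product encodes the
antipodal symmetry of diffusion weighting): a mixture of an exponential
term exp(-theta/ell) (full rank, so the exact-interpolation limit
holds) and a degree-2 Legendre term P2(cos theta) (the covariance of a
random second-order spherical-harmonic field, which is the angular
structure of single-tensor diffusion signals).  There is no covariance
across shells beyond a shared per-shell mean, and b=0 volumes are
predicted by their mean.  Hyperparameters are set by method of moments
plus a leave-one-out grid search over the mixture weight and
length-scale.

The per-voxel predictive mean is a linear combination of the training
volumes with weights that depend only on the descriptors, so prediction
is a pure q-space interpolation whenever the training volumes are
mutually aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .scheme import B0_THRESHOLD, DiffusionDescriptor, DiffusionScheme

__all__ = ["PredictorConfig", "PredictionMaker", "fit_predictor", "predict_volume"]


@dataclass
class PredictorConfig:
    """Hyperparameter policy for the q-space predictor.

    ``length_scales`` (radians) and ``sh_weights`` (mixture weight of
    the degree-2 spherical-harmonic covariance term, in [0, 1)) span the
    leave-one-out grid search.  ``noise_var``/``signal_var``/
    ``length_scale``/``sh_weight`` override the estimates when given.
    ``jitter`` is the relative diagonal loading applied before
    factorisation.
    """

    length_scales: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.6, 1.2, 2.0])
    )
    sh_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.3, 0.6, 0.9])
    )
    noise_var: float | None = None
    signal_var: float | None = None
    length_scale: float | None = None
    sh_weight: float | None = None
    jitter: float = 1e-6


def _angles(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Pairwise angular distances arccos(|g . g'|), antipodally symmetric."""
    d = np.abs(g1 @ g2.T)
    return np.arccos(np.clip(d, 0.0, 1.0))


def _kernel(theta: np.ndarray, sf2: float, ell: float, w: float = 0.0) -> np.ndarray:
    """Mixture covariance: exponential in angle plus degree-2 Legendre.

    ``P2(cos theta)`` is offset to be a valid (nonnegative-coefficient)
    spherical covariance; ``w`` is the Legendre mixture weight.
    """
    c = np.cos(theta)
    p2 = 0.5 * (3.0 * c**2 - 1.0)
    leg = (0.3 + 0.7 * p2) / 1.0
    return sf2 * ((1.0 - w) * np.exp(-theta / ell) + w * leg)


@dataclass
class _ShellModel:
    bval: float
    indices: np.ndarray
    bvecs: np.ndarray
    mean: np.ndarray          # (nvox,)
    resid: np.ndarray         # (n, nvox)
    sf2: float = 0.0
    sn2: float = 0.0
    ell: float = 1.0
    sh_w: float = 0.0
    cho: tuple | None = None


class PredictionMaker:
    """Fitted q-space interpolator; see module docstring.

    Use :func:`fit_predictor` to construct one.
    """

    def __init__(self, grid_shape, shells, b0):
        self.grid_shape = tuple(grid_shape)
        self._shells = shells      # list[_ShellModel] for b > 0
        self._b0 = b0              # _ShellModel with cho=None (mean predictor)

    # -- interrogation ------------------------------------------------
    @property
    def shell_bvals(self) -> list[float]:
        return [s.bval for s in self._shells]

    def hyperparameters(self, bval: float) -> dict:
        s = self._find_shell(bval)
        return {
            "signal_var": s.sf2,
            "noise_var": s.sn2,
            "length_scale": s.ell,
            "sh_weight": s.sh_w,
        }

    def _find_shell(self, bval: float) -> _ShellModel:
        if bval <= B0_THRESHOLD:
            return self._b0
        for s in self._shells:
            if abs(bval - s.bval) <= 0.10 * s.bval:
                return s
        raise ValueError(
            f"b-value {bval} is >10% away from every trained shell "
            f"({[s.bval for s in self._shells]})"
        )

    # -- prediction ---------------------------------------------------
    def weights(self, d_star: DiffusionDescriptor) -> tuple[np.ndarray, np.ndarray]:
        """Training-volume indices and their prediction weights for ``d_star``.

        The prediction is ``mean + sum_i w_i (f_i - mean)`` over the
        shell's volumes; weights depend only on descriptors.
        """
        s = self._find_shell(d_star.bval)
        if s.cho is None:  # b=0: shrunk mean, zero weights on residuals
            return s.indices, np.zeros(len(s.indices))
        theta = _angles(d_star.bvec[None, :], s.bvecs)[0]
        kstar = _kernel(theta, s.sf2, s.ell, s.sh_w)
        w = cho_solve(s.cho, kstar)
        return s.indices, w

    def predict(self, d_star: DiffusionDescriptor) -> np.ndarray:
        """Predicted complete volume on the regular grid for ``d_star``."""
        s = self._find_shell(d_star.bval)
        _, w = self.weights(d_star)
        flat = s.mean + w @ s.resid
        return flat.reshape(self.grid_shape)

    def residual_mss(self, volumes: np.ndarray, i: int, mask=None) -> float:
        """Mean squared difference between volume ``i`` and its prediction."""
        pred = self.predict_index(i)
        diff = np.asarray(volumes[i], dtype=float) - pred
        if mask is not None:
            diff = diff[mask]
        return float(np.mean(diff**2))

    def predict_index(self, i: int) -> np.ndarray:
        return self.predict(self._descriptors[i])

    def predict_loo(self, i: int) -> np.ndarray:
        """Prediction for training volume ``i`` with volume i left out.

        The registration target during estimation: using the volume's
        own data in its prediction would let it "match" its own
        misalignment, which matters when shells are small.  Shell
        hyperparameters are kept from the full fit.
        """
        d = self._descriptors[i]
        s = self._find_shell(d.bval)
        pos = np.flatnonzero(s.indices == i)
        if pos.size == 0:
            return self.predict(d)
        j = int(pos[0])
        keep = np.arange(len(s.indices)) != j
        vols = s.mean + s.resid            # training volumes of the shell
        mean_loo = vols[keep].mean(axis=0)
        if s.cho is None:                  # b=0 group: leave-one-out mean
            return mean_loo.reshape(self.grid_shape)
        g = s.bvecs[keep]
        theta = _angles(g, g)
        K = _kernel(theta, s.sf2, s.ell, s.sh_w) + s.sn2 * np.eye(keep.sum())
        K[np.diag_indices_from(K)] += 1e-6 * np.mean(np.diag(K))
        kstar = _kernel(_angles(d.bvec[None, :], g)[0], s.sf2, s.ell, s.sh_w)
        w = cho_solve(cho_factor(K), kstar)
        flat = mean_loo + w @ (vols[keep] - mean_loo)
        return flat.reshape(self.grid_shape)


def fit_predictor(
    volumes: np.ndarray,
    scheme: DiffusionScheme,
    config: PredictorConfig | None = None,
) -> PredictionMaker:
    """Fit the q-space predictor to (volume, descriptor) training pairs.

    ``volumes``: 4D array, first axis the volume index, aligned on the
    regular grid.  Requires at least two volumes per shell group.
    """
    config = config or PredictorConfig()
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {volumes.shape}")
    if volumes.shape[0] != scheme.n_volumes:
        raise ValueError(
            f"{volumes.shape[0]} volumes but scheme lists {scheme.n_volumes}"
        )
    grid_shape = volumes.shape[1:]
    flat = volumes.reshape(volumes.shape[0], -1)

    b0_idx = np.flatnonzero(scheme.is_b0)
    if b0_idx.size < 2:
        raise ValueError(f"need >= 2 b=0 volumes, got {b0_idx.size}")
    b0_mean = flat[b0_idx].mean(axis=0)
    b0 = _ShellModel(0.0, b0_idx, scheme.bvecs[b0_idx], b0_mean,
                     flat[b0_idx] - b0_mean)

    shells = []
    for bval, idx in scheme.shells().items():
        if bval <= B0_THRESHOLD:
            continue
        if idx.size < 2:
            raise ValueError(
                f"shell b={bval:.0f} has {idx.size} volume(s); need >= 2"
            )
        g = scheme.bvecs[idx]
        mean = flat[idx].mean(axis=0)
        resid = flat[idx] - mean
        s = _ShellModel(float(bval), idx, g, mean, resid)
        _fit_shell(s, config)
        shells.append(s)

    pm = PredictionMaker(grid_shape, shells, b0)
    pm._descriptors = [scheme.descriptor(i) for i in range(scheme.n_volumes)]
    return pm


def _fit_shell(s: _ShellModel, config: PredictorConfig) -> None:
    n = len(s.indices)
    theta = _angles(s.bvecs, s.bvecs)

    sf2 = config.signal_var
    if sf2 is None:
        # mean across-voxel variance of the residual volumes
        sf2 = float(np.mean(s.resid**2) * n / max(n - 1, 1))
    sn2 = config.noise_var
    if sn2 is None:
        # half the minimum nearest-neighbour mean squared difference
        off = theta + np.diag(np.full(n, np.inf))
        nn = np.argmin(off, axis=1)
        d2 = np.mean((s.resid - s.resid[nn]) ** 2, axis=1)
        sn2 = 0.5 * float(d2.min())
    sf2 = max(sf2, 1e-30)
    sn2 = max(sn2, 0.0)

    ell, sh_w = config.length_scale, config.sh_weight
    if ell is None or sh_w is None:
        ell, sh_w = _loo_kernel_search(theta, s.resid, sf2, sn2, config)
    s.sf2, s.sn2, s.ell, s.sh_w = float(sf2), float(sn2), float(ell), float(sh_w)

    K = _kernel(theta, sf2, ell, sh_w) + sn2 * np.eye(n)
    K[np.diag_indices_from(K)] += config.jitter * np.mean(np.diag(K))
    try:
        s.cho = cho_factor(K)
    except np.linalg.LinAlgError as e:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            f"shell b={s.bval:.0f}: covariance singular after jitter "
            f"(sf2={sf2:.3g}, sn2={sn2:.3g}, ell={ell:.3g}): {e}"
        ) from e


def _loo_kernel_search(theta, resid, sf2, sn2, config):
    """Grid-search kernel parameters minimising leave-one-out error."""
    n = theta.shape[0]
    ells = np.asarray(config.length_scales, dtype=float)
    if config.length_scale is not None:
        ells = np.array([config.length_scale])
    shws = np.asarray(config.sh_weights, dtype=float)
    if config.sh_weight is not None:
        shws = np.array([config.sh_weight])
    best, best_sse = None, np.inf
    for sh_w in shws:
        for ell in ells:
            K = _kernel(theta, sf2, ell, sh_w) + sn2 * np.eye(n)
            K[np.diag_indices_from(K)] += config.jitter * np.mean(np.diag(K))
            try:
                A = np.linalg.inv(K)
            except np.linalg.LinAlgError:
                continue
            loo = (A @ resid) / np.diag(A)[:, None]
            sse = float(np.sum(loo**2))
            if sse < best_sse:
                best, best_sse = (ell, sh_w), sse
    if best is None:
        raise np.linalg.LinAlgError("no kernel parameters yielded an invertible covariance")
    return best


def predict_volume(pm: PredictionMaker, d_star: DiffusionDescriptor) -> np.ndarray:
    """Predicted complete volume for diffusion descriptor ``d_star``."""
    return pm.predict(d_star)
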