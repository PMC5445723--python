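"""Synthetic multi-shell DWI phantoms with movement, dropout and noise.

Everything the correction pipeline consumes can be generated here with
known ground truth: an anisotropic digital phantom (ellipsoidal "brain"
containing crossing tract bundles, a CSF-like blob and isotropic
tissue), smooth six-parameter movement traces sampled at slice/MB-group
excitation times, interleaved single-band or multi-band slice ordering,
movement-coupled slice dropout, and additive Gaussian noise calibrated
to a target b=0 SNR.

Per-voxel signals follow the single-tensor model
``S = S0 exp(-b g^T D g)``; partial-volume voxels at region boundaries
mix the region signals, as real voxels do.  The default "desk-scale"
acquisition (6 b=0 + 24 b=700 volumes on a 48 x 48 x 30 grid of 2.5 mm
voxels, interleaved) keeps simulations tractable; a "full-scale"
scheme constant records the reference design (12 b=0 + 32 b=700 +
64 b=2000 at 2.5 mm) for users with more patience.

All randomness is seeded and two runs with equal seeds are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .resampling import predict_observed_slice
from .scheme import DiffusionScheme
from .temporal import SliceTiming

__all__ = [
    "PhantomSpec",
    "MovementTraceSpec",
    "DropoutSpec",
    "Phantom",
    "SimulatedDataset",
    "make_directions",
    "make_scheme",
    "full_scale_scheme",
    "make_phantom",
    "make_movement_trace",
    "simulate_acquisition",
    "add_dropout",
    "add_noise",
    "simulate_dataset",
]

#: eigenvalues (mm^2/s) of the tissue compartments
_D_TISSUE_ISO = 0.7e-3
_D_CSF_ISO = 2.5e-3
_D_TRACT = (1.7e-3, 0.25e-3, 0.25e-3)


@dataclass
class PhantomSpec:
    """Geometry and tissue layout of the digital phantom.

    The brain is an ellipsoid strictly inside the grid; two prolate
    tract bundles cross inside it and a bright CSF-like blob provides
    b=0 contrast so that rotations are well constrained even for
    unweighted volumes.
    """

    shape: tuple = (48, 48, 30)
    voxel_size: float = 2.5
    s0_tissue: float = 100.0
    s0_csf: float = 140.0
    s0_tract: float = 90.0
    brain_axes_frac: tuple = (0.80, 0.70, 0.78)
    smooth_voxels: float = 0.8

    def __post_init__(self):
        self.shape = tuple(int(d) for d in self.shape)
        if any(d <= 0 for d in self.shape) or len(self.shape) != 3:
            raise ValueError(f"invalid grid shape {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class MovementTraceSpec:
    """Smooth random subject-movement trace over excitation times.

    ``amplitude`` 1.0 gives "normal" movement with peak excursions of
    about 1 mm / 1 degree per parameter; 3.0 gives the "large" (bad
    movement) condition, exactly three times the normal trace at equal
    seed.  ``smoothness`` is the temporal correlation length in
    excitation times.  No movement is injected during the first two
    volumes, so motion-free shape-reference candidates always exist.
    """

    amplitude: float = 1.0
    smoothness: float = 10.0
    seed: int = 0
    still_volumes: int = 2

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


@dataclass
class DropoutSpec:
    """Movement-coupled slice dropout.

    ``fraction`` is the target expected fraction of affected slices
    (default 3%, typical of mildly difficult subjects); dropout factors
    are drawn uniformly from ``factor_range``; when ``movement_coupled``
    the per-excitation dropout probability is proportional to the
    magnitude of the temporal derivative of the true movement.
    """

    fraction: float = 0.03
    factor_range: tuple = (0.1, 0.9)
    movement_coupled: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("dropout fraction must be in [0, 1]")
        lo, hi = self.factor_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("factor range must lie within [0, 1]")


@dataclass
class Phantom:
    truth: np.ndarray          # (n_vols, nx, ny, nz) noise-free series
    fa: np.ndarray             # true FA of the blended tensor field
    mask: np.ndarray           # brain mask
    tensors: np.ndarray        # (nx, ny, nz, 3, 3) blended diffusion tensors
    s0: np.ndarray             # (nx, ny, nz) blended S0


@dataclass
class SimulatedDataset:
    """One corrupted acquisition plus every piece of ground truth."""

    observed: np.ndarray
    phantom: Phantom
    scheme: DiffusionScheme
    timing: SliceTiming
    trace: np.ndarray              # (n_vols * n_times, 6) true movement
    sidecar: np.ndarray            # (n_vols, n_times, 6) per-excitation truth
    dropout_mask: np.ndarray       # (n_vols, n_slices) bool
    voxel_size: float
    noise_sd: float


# ---------------------------------------------------------------------------
# diffusion scheme
# ---------------------------------------------------------------------------

def make_directions(n: int, seed: int = 0, n_iter: int = 300) -> np.ndarray:
    """Gradient directions optimised on the half-sphere by Coulomb forces,
    then randomly sign-flipped over the whole sphere (seeded)."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    step = 0.5 / n
    for _ in range(n_iter):
        # antipodally symmetric repulsion: each point feels +/- of the others
        diff = g[:, None, :] - g[None, :, :]
        anti = g[:, None, :] + g[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1) + np.eye(n)
        d2 = np.linalg.norm(anti, axis=-1) + 1e-12
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            anti / d2[..., None] ** 3
        ).sum(axis=1)
        force -= (force * g).sum(axis=1, keepdims=True) * g  # tangential part
        # cap the displacement so close pairs do not overshoot past each other
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        force = force / np.maximum(norm, 1.0) * np.minimum(norm, 1.0)
        g = g + step * force
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    flip = rng.random(n) < 0.5
    g[flip] *= -1.0
    return g


def make_scheme(
    n_b0: int = 6,
    shells=((700.0, 24),),
    seed: int = 0,
) -> DiffusionScheme:
    """Interspersed b=0 volumes plus Coulomb-optimised shells.

    Volume 0 is always b=0 and volume 1 a DWI, so the two motion-free
    lead volumes provide a shape reference for both groups.
    """
    n_dwi = sum(n for _, n in shells)
    n_vols = n_b0 + n_dwi
    bvals = np.empty(n_vols)
    bvecs = np.zeros((n_vols, 3))
    b0_pos = np.unique(np.round(np.linspace(0, n_vols - 1, n_b0)).astype(int))
    # keep volume 1 diffusion-weighted
    if 1 in b0_pos and n_b0 > 1:
        b0_pos = np.array(sorted(set(b0_pos) - {1} | {2 if 2 not in b0_pos else 3}))
    dwi_pos = np.array([i for i in range(n_vols) if i not in set(b0_pos)])
    bvals[b0_pos] = 0.0
    dirs = []
    bs = []
    for k, (b, n) in enumerate(shells):
        dirs.append(make_directions(n, seed=seed + 7 * k))
        bs.append(np.full(n, float(b)))
    dirs = np.concatenate(dirs)
    bs = np.concatenate(bs)
    order = np.random.default_rng(seed + 101).permutation(n_dwi)
    bvals[dwi_pos] = bs[order]
    bvecs[dwi_pos] = dirs[order]
    return DiffusionScheme(bvals, bvecs)


def full_scale_scheme(seed: int = 0) -> DiffusionScheme:
    """The full-scale design: 12 interspersed b=0, 32 b=700 and 64 b=2000."""
    return make_scheme(n_b0=12, shells=((700.0, 32), (2000.0, 64)), seed=seed)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def _ellipsoid(shape, centre_frac, axes_frac) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c = np.array(centre_frac) * (np.array(shape) - 1)
    a = np.array(axes_frac) * np.array(shape) / 2.0
    q = ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
    return q <= 1.0


def _cylinder(shape, axis, centre_frac, radius_frac) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    coords = [x, y, z]
    c = np.array(centre_frac) * (np.array(shape) - 1)
    others = [i for i in range(3) if i != axis]
    r2 = sum(
        ((coords[i] - c[i]) / (radius_frac * shape[i])) ** 2 for i in others
    )
    return r2 <= 1.0


def _tensor(eigvals, axis) -> np.ndarray:
    d = np.diag(np.roll(np.asarray(eigvals, dtype=float), axis))
    return d


def make_phantom(spec: PhantomSpec, scheme: DiffusionScheme) -> Phantom:
    """Noise-free ground-truth series, true FA map and brain mask.

    Per voxel the signal is the partial-volume mixture over regions r of
    ``w_r S0_r exp(-b g^T D_r g)``; the true FA comes from the
    signal-weighted blended tensor.
    """
    shape = spec.shape
    brain = _ellipsoid(shape, (0.5, 0.5, 0.5), spec.brain_axes_frac)
    csf = _ellipsoid(shape, (0.42, 0.56, 0.52), (0.16, 0.20, 0.22)) & brain
    tract_x = _cylinder(shape, 0, (0.5, 0.40, 0.46), 0.11) & brain
    tract_y = _cylinder(shape, 1, (0.60, 0.5, 0.58), 0.11) & brain

    regions = {
        "tissue": (brain & ~(csf | tract_x | tract_y),
                   spec.s0_tissue, np.eye(3) * _D_TISSUE_ISO),
        "csf": (csf, spec.s0_csf, np.eye(3) * _D_CSF_ISO),
        "tract_x": (tract_x & ~csf, spec.s0_tract, _tensor(_D_TRACT, 0)),
        "tract_y": (tract_y & ~(csf | tract_x), spec.s0_tract, _tensor(_D_TRACT, 1)),
    }
    weights = {}
    for name, (m, _, _) in regions.items():
        weights[name] = ndimage.gaussian_filter(
            m.astype(float), spec.smooth_voxels
        )

    n_vols = scheme.n_volumes
    truth = np.zeros((n_vols,) + tuple(shape))
    s0_map = np.zeros(shape)
    num = np.zeros(shape + (3, 3))
    den = np.zeros(shape)
    for name, (m, s0, D) in regions.items():
        w = weights[name]
        s0_map += w * s0
        num += (w * s0)[..., None, None] * D
        den += w * s0
        # attenuation per volume for this region's single tensor
        att = np.exp(-scheme.bvals * np.einsum("ij,vi,vj->v", D, scheme.bvecs, scheme.bvecs))
        truth += (w * s0)[None, ...] * att[:, None, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        tensors = np.where(den[..., None, None] > 1e-9, num / den[..., None, None], 0.0)
    mask = den > 0.5 * spec.s0_tissue
    # the reference FA is fitted from the noise-free signals by the same
    # WLS pipeline the evaluation uses; in pure (single-compartment)
    # voxels it equals the eigenvalue FA of the known tensor
    from .evaluation import wls_tensor_fit

    _, fa = wls_tensor_fit(truth, scheme, mask)
    return Phantom(truth, fa, mask, tensors, s0_map)


def _fa_from_tensors(tensors: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvalsh(tensors)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5 * ((ev - md) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def make_movement_trace(
    spec: MovementTraceSpec, n_volumes: int, timing: SliceTiming
) -> np.ndarray:
    """Smooth seeded movement trace, one row per excitation time.

    An integrated Gaussian-increment walk per parameter is smoothed with
    a Gaussian kernel of width ``spec.smoothness`` excitations, windowed
    to zero over the first ``still_volumes`` volumes, and rescaled so
    the session peak excursion of each parameter equals
    ``amplitude x (1 mm or 1 degree)``.  Returns (n_volumes * N, 6) in
    mm and radians.
    """
    N = timing.n_times
    n_exc = n_volumes * N
    rng = np.random.default_rng(spec.seed)
    raw = np.cumsum(rng.standard_normal((n_exc, 6)), axis=0)
    raw = ndimage.gaussian_filter1d(raw, spec.smoothness, axis=0, mode="nearest")

    t0 = min(spec.still_volumes * N, n_exc)
    window = np.ones(n_exc)
    window[:t0] = 0.0
    ramp = min(max(N // 2, 1), max(n_exc - t0, 1))
    if t0 < n_exc:
        tr = np.arange(min(ramp, n_exc - t0))
        window[t0 : t0 + tr.size] = 0.5 * (1 - np.cos(np.pi * (tr + 1) / ramp))
    trace = (raw - raw[min(t0, n_exc - 1)]) * window[:, None]

    peak = np.max(np.abs(trace), axis=0)
    peak[peak == 0] = 1.0
    trace = trace / peak
    scale = np.array([1.0, 1.0, 1.0] + [np.deg2rad(1.0)] * 3) * spec.amplitude
    return trace * scale


def trace_to_sidecar(trace: np.ndarray, n_volumes: int, timing: SliceTiming):
    return np.asarray(trace, dtype=float).reshape(n_volumes, timing.n_times, 6)


# ---------------------------------------------------------------------------
# acquisition, dropout, noise
# ---------------------------------------------------------------------------

def simulate_acquisition(
    truth: np.ndarray,
    trace: np.ndarray,
    timing: SliceTiming,
    voxel_size=1.0,
    order: int = 3,
):
    """Sample every slice from its truth volume at its excitation-time pose.

    All slices of an MB group share one rigid configuration.  Returns
    ``(observed 4D series, sidecar)`` where the sidecar holds the true
    per-excitation parameters, shape (n_vols, N, 6).
    """
    truth = np.asarray(truth, dtype=float)
    n_vols = truth.shape[0]
    sidecar = trace_to_sidecar(trace, n_vols, timing)
    observed = np.empty_like(truth)
    for i in range(n_vols):
        vol_params = sidecar[i]
        if np.allclose(vol_params, 0.0):
            observed[i] = truth[i]
            continue
        pre = ndimage.spline_filter(truth[i], order=order, mode="nearest") \
            if order > 1 else truth[i]
        for s in range(timing.n_slices):
            sl, _ = predict_observed_slice(
                pre, vol_params, timing, s, voxel_size=voxel_size,
                order=order, prefiltered=order > 1,
            )
            observed[i][:, :, s] = sl
    return observed, sidecar


def add_dropout(
    series: np.ndarray,
    trace: np.ndarray,
    spec: DropoutSpec,
    timing: SliceTiming,
):
    """Multiply randomly selected slices/MB-groups by a dropout factor.

    Selection probability per excitation is proportional to the
    magnitude of the temporal derivative of the movement trace
    (rotations counted in degrees), normalised so the expected affected
    slice fraction equals ``spec.fraction``; a constant trace falls back
    to uniform selection.  Returns (series, mask, factors) with mask of
    shape (n_vols, n_slices).
    """
    series = np.array(series, dtype=float)
    n_vols = series.shape[0]
    N = timing.n_times
    rng = np.random.default_rng(spec.seed)
    sidecar = trace_to_sidecar(trace, n_vols, timing)

    if spec.movement_coupled:
        flat = sidecar.reshape(-1, 6).copy()
        flat[:, 3:] = np.rad2deg(flat[:, 3:])
        deriv = np.vstack([np.zeros((1, 6)), np.diff(flat, axis=0)])
        mag = np.sqrt(np.mean(deriv**2, axis=1))
    else:
        mag = np.ones(n_vols * N)
    if mag.sum() <= 0:
        mag = np.ones(n_vols * N)
    probs = spec.fraction * mag * (mag.size / mag.sum())
    probs = np.clip(probs, 0.0, 1.0)
    hit = rng.random(mag.size) < probs
    factors = rng.uniform(*spec.factor_range, size=mag.size)

    mask = np.zeros((n_vols, timing.n_slices), dtype=bool)
    for e in np.flatnonzero(hit):
        i, n = divmod(e, N)
        slices = list(timing.groups[n])
        series[i][:, :, slices] *= factors[e]
        mask[i, slices] = True
    return series, mask, factors


def add_noise(
    series: np.ndarray,
    snr_b0: float,
    seed: int,
    scheme: DiffusionScheme,
    mask: np.ndarray,
):
    """Additive Gaussian noise at a target b=0 SNR.

    Noise SD = mean in-brain b=0 intensity / snr_b0, independent per
    voxel and volume, seeded.  (Gaussian rather than Rician: at the
    SNR levels used, >= 20 for b=0, the difference is negligible.)
    Returns (noisy series, noise SD).
    """
    if not snr_b0 > 0:
        raise ValueError("SNR must be positive")
    series = np.asarray(series, dtype=float)
    rng = np.random.default_rng(seed)
    b0_mean = float(series[scheme.is_b0][:, mask].mean())
    sd = b0_mean / snr_b0
    return series + rng.standard_normal(series.shape) * sd, sd


# ---------------------------------------------------------------------------
# one-call dataset factory
# ---------------------------------------------------------------------------

def simulate_dataset(
    seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    scheme: DiffusionScheme | None = None,
    timing: SliceTiming | None = None,
    movement: str | float = "large",
    snr: float | None = 40.0,
    dropout: DropoutSpec | None = None,
    trace_smoothness: float = 10.0,
) -> SimulatedDataset:
    """Generate a complete corrupted dataset plus its ground truth.

    ``movement``: "normal" (amplitude 1), "large" (amplitude 3) or a
    numeric amplitude; ``snr=None`` for noise-free data; ``dropout=None``
    for no dropout.
    """
    phantom_spec = phantom_spec or PhantomSpec()
    scheme = scheme if scheme is not None else make_scheme(seed=seed)
    nz = phantom_spec.shape[2]
    timing = timing or SliceTiming.interleaved(nz)
    amplitude = {"normal": 1.0, "large": 3.0}.get(movement, movement)
    phantom = make_phantom(phantom_spec, scheme)

    tspec = MovementTraceSpec(
        amplitude=float(amplitude), smoothness=trace_smoothness, seed=seed
    )
    trace = make_movement_trace(tspec, scheme.n_volumes, timing)
    observed, sidecar = simulate_acquisition(
        phantom.truth, trace, timing, voxel_size=phantom_spec.voxel_size
    )
    if dropout is not None:
        observed, dmask, _ = add_dropout(observed, trace, dropout, timing)
    else:
        dmask = np.zeros((scheme.n_volumes, timing.n_slices), dtype=bool)
    noise_sd = 0.0
    if snr is not None:
        observed, noise_sd = add_noise(
            observed, snr, seed + 2**20, scheme, phantom.mask
        )
    return SimulatedDataset(
        observed=observed,
        phantom=phantom,
        scheme=scheme,
        timing=timing,
        trace=trace,
        sidecar=sidecar,
        dropout_mask=dmask,
        voxel_size=phantom_spec.voxel_size,
        noise_sd=noise_sd,
    )
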