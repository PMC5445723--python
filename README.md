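# s2v — slice-to-volume movement correction for diffusion MRI

Diffusion-weighted volumes are acquired slice by slice over several
seconds. When the subject moves *within* that window — common with
infants, children, elderly or simply restless subjects — the slices are
no longer parallel planes of one rigid head: interleaved acquisitions
show the characteristic jagged edges, and ordinary volume-to-volume
realignment can only park the whole misassembled stack at a compromise
position. Downstream scalar maps such as fractional anisotropy (FA)
inherit the damage, which is a known source of spurious group
differences when movement correlates with the condition under study.

`s2v` raises the temporal resolution of motion correction to the slice
(or multi-band group) level:

* **Movement model** — each of the six rigid parameters is a truncated
  discrete-cosine series over the volume's excitation times,
  `r_p(n) = Σ_k B[k,p] cos(k n π/(N−1))`; order 0 reproduces the
  volumetric model, and a second-derivative penalty (weight `λ`) keeps
  the trace physically smooth.
* **Registration target** — a Gaussian-process q-space interpolator
  predicts, for any b-value and gradient direction, what the
  corresponding volume should look like; each volume is registered to
  its leave-one-out prediction by Gauss–Newton on the forward model
  that samples the prediction at rigidly transformed slice positions.
* **Reconstruction** — observed slices are mapped back to the regular
  grid by a hybrid 2D+1D scheme: a closed form gives the through-plane
  coordinate z\* of every slice sample, 2D spline interpolation gives
  its intensity, and a regularised irregular cubic-B-spline fit per
  (x, y) column resamples onto integer z, with sampling gaps filled by
  prediction values whose weights ensure observations always take
  precedence.
* **Synthetic data** — a multi-shell digital phantom with crossing
  tract bundles, smooth seeded movement traces, interleaved single-band
  or multi-band timing, movement-coupled slice dropout and calibrated
  noise makes every stage verifiable without scanner data.

See `docs/methods.md` for the model details, parameter choices and
limitations.

## Worked example

```python
import numpy as np
from s2v.synthetic import PhantomSpec, make_scheme, simulate_dataset
from s2v.temporal import SliceTiming
from s2v.estimation import EstimationConfig, run_correction
from s2v.evaluation import per_volume_rmse

# the standard verification condition: 48x48x30 phantom at 2.5 mm,
# 6 b=0 + 24 b=700 volumes, interleaved single-band, "large"
# (3 mm / 3 deg) movement, b0-SNR 40
ds = simulate_dataset(seed=1, movement="large", snr=40.0)

result = run_correction(
    ds.observed, ds.scheme, ds.timing,
    EstimationConfig(dof=8, lam=1.0),      # 8 DCT terms per parameter
    voxel_size=ds.voxel_size,
)
report = per_volume_rmse(ds.sidecar, result.motion, ds.timing,
                         result.included_slices)
print(f"translation RMSE: {report.translation_mm:.4f} mm")
print(f"rotation RMSE:    {report.rotation_deg:.4f} deg")
```

Output:

```
translation RMSE: 0.1416 mm
rotation RMSE:    0.2656 deg
```

The numbers are the slice-wise root-mean-square differences between the
estimated and the true movement parameters, averaged over axes and
volumes (slices with an appreciable amount of phantom only): every
slice's estimated position is compared against the position the
simulator actually gave it. For contrast, a volume-to-volume correction
of the same data (`dof=1`) reaches about 0.16 mm / 0.29 deg, and the
uncorrected intra-volume movement itself has a within-volume spread of
up to ~0.5 deg — `result.corrected` holds the reconstructed series and
`result.motion_table(ds.timing)` the time-resolved movement estimates
in mm and degrees.

The same interface works from the shell:

```bash
s2v simulate --seed 1 --out-dir sim/
s2v correct --in sim/dwi.nii.gz --bvals sim/bvals --bvecs sim/bvecs \
    --slice-order sim/slice_order.txt --dof 8 --lambda 1 \
    --out corrected.nii.gz --motion-out motion.tsv
s2v evaluate --truth-motion sim/true_motion.tsv --est-motion motion.tsv \
    --slice-order sim/slice_order.txt --n-slices 30 --n-times 30 \
    --out report.json
```

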