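# cardiomicro

Quantitative cardiac MR analysis of the infarcted left ventricle, verified end
to end against a synthetic phantom.

After a myocardial infarction, the heart remodels across scales: oedema raises
T2 acutely; cell death and matrix deposition raise the extracellular volume
fraction (ECV) and mean diffusivity (MD) and lower fractional anisotropy (FA)
chronically; the transmural helix-angle (HA) architecture steepens while
torsion and longitudinal strain fall. `cardiomicro` implements the full
analysis toolchain for a longitudinal study of this process — relaxometry,
diffusion-tensor microstructure, ventricular function, late-gadolinium scar
quantification and the comparison statistics — and couples it to a digital
left-ventricle phantom that forward-simulates every acquisition from known
regional ground truth over an acute-to-chronic timeline (baseline, day 6,
week 5, week 9; control and infarct cohorts). Because the phantom's truth is
known, every fitting stage is testable by parameter recovery, without any
animal data.

## Models at the core

- **T1 (MOLLI)** — per-voxel magnitude fit of |A − B·e^(−TI/T1\*)| with
  polarity restoration and the Look-Locker correction T1 = T1\*(B/A − 1).
- **T2** — weighted log-linear mono-exponential fit of S0·e^(−TE/T2) over nine
  echoes (ΔTE 8.8 ms), optional constant-offset variant.
- **ECV** — (1 − Hct)·ΔR1_myo/ΔR1_blood from pre/post-contrast T1, clipped to
  [0, 1].
- **Diffusion tensor** — weighted linear least squares on ln S over an
  18-direction, 3-shell scheme (3 @ b100, 3 @ b200, 12 @ b450 s/mm², 8
  averages); MD = tr(D)/3, FA from the eigenvalue dispersion; helix angle from
  the primary eigenvector projected into the circumferential–longitudinal
  surface; transmural HA gradient as the OLS slope of HA against wall depth
  (°/%) in the septal AHA segments 8–9.
- **Function** — Simpson volumes/EF from cavity masks; torsion as the slope of
  slice rotation vs initial longitudinal position (°/mm); simplified
  geometric contour strains (GRS/GCS/GLS).
- **Scar** — LGE thresholding at mean + 5·SD of remote signal; mass via
  1.05 g/ml myocardial density, reported as % of LV mass.
- **Statistics** — paired/unpaired two-tailed Student's t-tests, relative
  change normalised to the reference region, all-pairs control-vs-remote bias,
  Pearson correlations with 95 % CI bands.

## Worked example

```python
import numpy as np
from cardiomicro import diffusion as dti, relaxometry
from cardiomicro.config import default_phantom_config
from cardiomicro.phantom import (build_phantom, make_tensor_field,
                                 simulate_dwi, simulate_multiecho)

cfg = default_phantom_config("infarct", grid_size=64, n_slices=6)
gt = build_phantom(cfg, "day6")

series = simulate_multiecho(gt.t2, mask=gt.myocardium, s0=1000.0,
                            noise_sigma=1000.0 / 30.0, seed=1)
t2 = relaxometry.fit_t2_map(series, gt.myocardium)
print(f"day-6 T2: infarct {np.nanmean(t2[gt.infarct]):.1f} ms, "
      f"remote {np.nanmean(t2[gt.remote]):.1f} ms")

protocol = dti.default_protocol()
b100 = 1000.0 * np.exp(-100.0 * gt.md[gt.myocardium]).mean()
dwi = simulate_dwi(make_tensor_field(gt), protocol, s0=1000.0,
                   noise_sigma=b100 / 30.0, seed=1)
tf = dti.fit_diffusion_tensor(dwi, protocol, gt.myocardium)
md, fa = dti.tensor_metrics(tf)
ha = dti.helix_angle_map(tf, gt.frames)
grad = dti.transmural_ha_gradient(ha, gt.frames, gt.aha)
print(f"day-6 MD: infarct {1e3*np.mean(md[gt.infarct]):.2f} x1e-3 mm^2/s")
print(f"septal HA gradient: {grad.slope_deg_per_pct:.3f} deg/%")
```

Output:

```
day-6 T2: infarct 84.3 ms, remote 62.1 ms
day-6 MD: infarct 1.40 x1e-3 mm^2/s
septal HA gradient: -1.164 deg/%
```

The infarct ROI recovers the configured acute-oedema T2 (83 ms) and elevated
MD (1.404 × 10⁻³ mm²/s) within noise, and the septal HA regression returns the
prescribed −1.16 °/% transmural slope.

A whole simulated study (4 controls, 5 infarct animals, 4 timepoints) runs
from the command line:

```sh
cardiomicro run --out study/ --seed 1
cardiomicro phantom simulate --timepoint day6 --out sim/   # NIfTI + bval/bvec + contours
```

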