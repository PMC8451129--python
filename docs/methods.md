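# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `cardiomicro`. Units throughout: lengths in mm, times in
ms, diffusivities in mm²/s, angles in degrees.

## The phantom

The digital left ventricle is a stack of short-axis annuli ordered apex →
base, with per-slice longitudinal position z_s = s·(slice thickness + gap).
Defaults follow a clinical 1.5 T protocol: 2 × 2 mm² in-plane resolution,
8 mm slices, 10 slices, 96 × 96 grid, endo/epi radii 20/30 mm with an optional
linear apex taper. The AHA 16-segment ring scheme parcellates the wall (basal
and mid rings of six 60° segments, apical ring of four 90° segments),
referenced to a configurable RV-insertion angle; the septum is segments 8–9.
The infarct territory is an angular sector of the inferolateral wall over a
slice range (defaults: 79.2° over half the slices, ≈ 11 % of myocardial
voxels, matching the LGE-based ischemic-region size it must reproduce), kept
disjoint from the septal segments because the transmural HA analysis uses the
septum as the remote reference.

Transmural depth runs from 0 % at the endocardial border to 100 % at the
epicardial border, measured along the centroid ray between the two contour
crossings. The helix angle ramps linearly in depth between per-timepoint
endpoints ha_endo > 0 > ha_epi (right-handed subendocardium, left-handed
subepicardium), so the prescribed transmural gradient is
(ha_epi − ha_endo)/100 °/%.

### Regional ground truth

Per timepoint and region (remote, infarct, blood) the phantom prescribes
native and post-contrast T1, T2, MD, FA and a scar flag. The default timeline
encodes the acute-to-chronic infarction course: T2 peaks acutely (83 ms
infarct vs 61 ms remote at day 6, normalising thereafter); native infarct T1
stays in a narrow 1099–1128 ms band from acute to chronic; infarct MD rises
by +17/+33/+29 % and FA falls by −31/−38/−36 % (day 6/week 5/week 9) relative
to the pre-infarct state; infarct ECV rises from 0.24 by +125/+157/+146 %.
The published source for this timeline prints the relative changes but not
the absolute healthy-tissue values, so the remote/control defaults are
field-typical 1.5 T in-vivo values chosen once — native T1 960 ms, T2 58 ms,
MD 1.2 × 10⁻³ mm²/s, FA 0.45, ECV 0.24, blood T1 1600 → 280 ms, hematocrit
0.33 — and every absolute infarct value is derived from them through the
printed relative quantities (with native T1 960 ms, the chronic infarct T1 of
1128 ms also reproduces the reported 17–18 % T1 contrast). Post-contrast T1
ground truths are obtained by inverting the ECV formula, which closes the
MOLLI → T1 → ECV recovery chain exactly.

### Forward models

- **DWI**: S = S0·exp(−b·gᵀDg) over 3 directions @ b = 100, 3 @ 200 and 12 @
  450 s/mm² with 8 signal averages. Tensors are built axially symmetric with
  λ1 = MD(1 + 2δ), λ2 = λ3 = MD(1 − δ), δ = FA/√(3 − 2 FA²), primary
  eigenvector at the prescribed helix angle in the circumferential–
  longitudinal plane; recomputing MD/FA from the tensor reproduces the inputs
  to machine precision. No b = 0 volume is acquired (the lowest shell is
  b = 100), so ln S0 is an unknown of the fit.
- **Inversion recovery (MOLLI-like)**: |A − B·e^(−TI/T1*)| with perfect
  inversion B = 2A by default (imperfect inversion available); under B = 2A
  the Look-Locker identity makes T1* = T1. Default delays: 11 pre-contrast
  (100–4000 ms), 13 shorter post-contrast (80–2000 ms).
- **Multi-echo T2**: S0·e^(−TE/T2), nine echoes at multiples of 8.8 ms.
- **LGE**: remote myocardium ~ N(μ, σ), scar at μ + 15σ (well above the 5SD
  threshold), bright blood pool, dim background.
- **Contour motion**: slice s rotates by torsion·z_s·w(t), where w is a
  smooth 0 → 1 → 0 activation peaking at 35 % of the cycle (26 phases) and
  renormalised so its discrete maximum is exactly 1 — the prescribed peak
  torsion and strains are then attained at a sampled phase and the noiseless
  round trip is exact. Mid-wall radius scales with GCS, wall thickness with
  GRS, and a long-axis landmark polyline with GLS; cavity masks are
  rasterised from the endocardial contours.
- **Noise**: magnitude-MR (Rician), the modulus of (S + n₁, n₂) with
  n ~ N(0, σ). The published study states no DWI SNR; the default is SNR 30
  (σ = reference signal/30, referenced to the b = 100 shell mean for DWI),
  chosen once so ROI recovery sits within the study's reported SDs. All
  randomness is seeded; reruns are bit-identical.

## Fitting stages

**T1.** For fixed T1* the signed model A − B·e^(−TI/T1*) is linear in (A, B),
so the three-parameter fit reduces to a 1-D search over T1*: every "first k
samples inverted" polarity hypothesis is scored on a 160-point log grid
(20–8000 ms), and the winner is refined by 90 vectorised golden-section
iterations. This is exact at zero noise (the round-trip tests assert 1e−9
relative) and needs no per-voxel Python optimiser. Voxels with A ≤ 0, B ≤ 0
or non-positive T1 are flagged invalid and excluded from ROI means.

**T2.** Weighted log-linear least squares with weights S² (the first-order
variance correction for log-transformed magnitude data); non-positive samples
are excluded per voxel, voxels with fewer than 3 usable echoes are invalid.
The published fit model (with or without constant offset) is not stated; the
default is the 2-parameter mono-exponential, with a 3-parameter nonlinear
offset variant available.

**Tensor.** Weighted linear least squares on ln S for
[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz], weights S²; protocol rank is validated
up front (≥ 6 unique directions over ≥ 2 shells), signals ≤ ε are clipped and
flagged. Eigenvalues are sorted descending; FA is clipped to [0, 1] and
negative eigenvalues (noise) flagged; the all-zero tensor has FA = 0.

**Helix angle.** e1 is projected onto the circ–long surface; antipodal
ambiguity is resolved by flipping e1 so the circumferential component is
non-negative, with the ±90° tie broken toward a non-negative longitudinal
component (continuity at the boundary). Voxels whose projection norm falls
below 0.2 (dominantly radial e1) are masked; this threshold is a package
choice — the source does not state one. The gradient is regressed in percent
depth (not mm) to match the °/% reporting convention, in segments 8–9 only:
the infarcted lateral wall is too thin for a reliable transmural regression.

**Registration.** Phantom series are co-registered by construction, so
pre/post T1 registration is the identity; real inputs are the caller's
responsibility. Torsion uses the *initial* longitudinal position as
regressor, rotation is counterclockwise-positive viewed from the apex, and
the reported peak is the cycle maximum of |slope| at its signed value.
Feature-tracking strain software is intentionally replaced by transparent
geometric contour strains (perimeter/thickness/landmark length); these are
simplified and are validated only against the phantom's own prescription.

**Scar.** Threshold = remote mean + 5·SD (volumetric SD estimate; slice-wise
estimation is not implemented). Manual refinement is replaced by an optional
largest-connected-component filter, off by default and logged when used.
Tissue density 1.05 g/ml (standard myocardial value, not stated in the
source).

**Statistics.** Paired contrasts use within-subject pairs; the unpaired test
is classical pooled-variance Student (not Welch). Relative change is
(x_infarct − x_ref)/x_ref per subject; the bias statistic enumerates all
(control, infarct) pairs normalised by the pair mean. Pearson correlation
p-values come from t = r√((n−2)/(1−r²)); the 95 % CI band is the pointwise
OLS mean band. No multiple-testing correction is applied, mirroring the study
design; outputs carry that flag. Correlation row selection is explicit
(callers choose which timepoints/regions to pool) because the study's pooling
is ambiguous.

## Problem sizes

The full-protocol study (96 × 96 grid, 10 slices, 4 + 5 subjects, 4
timepoints, every modality) runs in a few minutes on one CPU. The package's
recovery experiments and test suite use reduced grids chosen once — 64 × 64
with 6 slices for the recovery experiments, 48 × 48 or 36 × 36 with 1–3
slices for unit tests — which leave 300–400 infarct voxels per ROI, ample for
ROI-mean statistics at SNR 30. The scar-recovery experiment searches the
sector width over a ±8° window so the digitised scar occupies the target
fraction of myocardial voxels as closely as the grid allows.

## What the phantom does and does not emulate

It emulates: regional contrasts and their longitudinal evolution, the
transmural HA architecture, realistic acquisition protocols, Rician noise,
prescribed torsion/strain kinematics, and enhanced scar with a nulled remote.
It does not emulate: k-space/EPI artefacts, off-resonance distortion, motion
between frames, partial-volume mixing beyond grid digitisation, non-circular
wall geometry, papillary muscles, heart-rate-dependent MOLLI sampling,
stimulated echoes in T2 decay, or between-modality mis-registration.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every in-vivo confound.

Known numerical caveats: the Rician noise floor biases late echoes upward, so
fitted T2 carries a small positive bias (≈ +1.5 % at SNR 30, within the
recovery tolerance); the same applies weakly to the high-b DWI shell.
Per-subject biological variation in the study simulator is a single
multiplicative factor per parameter (stable animal-level offset), which
preserves within-subject contrasts and under-disperses between-subject SDs
relative to real cohorts.
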