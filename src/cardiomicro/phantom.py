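"""Synthetic left-ventricle phantom and forward simulators.

The phantom is a stack of short-axis annuli (apex -> base) with an AHA
16-segment ring parcellation, an inferolateral infarct territory over a
configurable sector and slice range, per-voxel ground-truth maps (native and
post-contrast T1, T2, MD, FA, helix angle, scar flag), and forward models for
every acquisition the analysis pipeline consumes: multi-shell DWI, inversion
recovery (MOLLI-style), multi-echo T2 decay, late gadolinium enhancement, and
tracked contour motion with prescribed torsion and global strains.

Noise model: magnitude MR (Rician) noise, implemented as the modulus of the
signal plus two independent Gaussian channels.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _sk_polygon

from .config import PhantomConfig, RegionValues, TimepointSpec
from .containers import ImageSeries
from .diffusion import (
    DiffusionProtocol,
    LVFrameField,
    TensorField,
    default_protocol,
    local_coordinate_frame,
)
from .mechanics import TrackedContours

__all__ = [
    "GroundTruth",
    "build_phantom",
    "make_tensor_field",
    "simulate_dwi",
    "simulate_molli",
    "simulate_multiecho",
    "simulate_lge",
    "simulate_contour_motion",
    "simulate_cavity_masks",
    "default_inversion_times",
    "default_echo_times",
]

SEPTAL_SEGMENTS = (8, 9)

# within-ring segment order, counterclockwise from the RV-insertion reference
_RING6 = ("anterior", "anteroseptal", "inferoseptal",
          "inferior", "inferolateral", "anterolateral")


@dataclass
class GroundTruth:
    """Masks, labels and ground-truth parameter maps for one timepoint."""

    config: PhantomConfig
    timepoint: TimepointSpec
    myocardium: np.ndarray  # bool (nz, ny, nx)
    blood: np.ndarray
    infarct: np.ndarray
    remote: np.ndarray  # myocardium outside the infarct territory
    aha: np.ndarray  # int labels 1-16, 0 outside myocardium
    t1_native: np.ndarray
    t1_post: np.ndarray
    t2: np.ndarray
    md: np.ndarray
    fa: np.ndarray
    ha: np.ndarray  # degrees, NaN outside myocardium
    scar: np.ndarray
    depth_pct: np.ndarray
    frames: LVFrameField
    z_mm: np.ndarray
    endo_radius_mm: np.ndarray
    epi_radius_mm: np.ndarray
    endo_contours: list = field(default_factory=list)
    epi_contours: list = field(default_factory=list)

    @property
    def septum(self) -> np.ndarray:
        return np.isin(self.aha, SEPTAL_SEGMENTS)

    @property
    def grid_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.config.grid_size
        ax = (np.arange(n) - (n - 1) / 2.0) * self.config.pixel_spacing_mm
        return np.meshgrid(ax, ax)  # X (cols), Y (rows)


def _circle_contour(radius: float, n_points: int = 90) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th)])


def _in_sector(theta_deg: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    lo, hi = sector[0] % 360.0, sector[1] % 360.0
    t = theta_deg % 360.0
    if lo <= hi:
        return (t >= lo) & (t < hi)
    return (t >= lo) | (t < hi)


def _aha_ring(slice_idx: int, n_slices: int) -> int:
    """0 = apical, 1 = mid, 2 = basal (slices ordered apex -> base)."""
    return min(2, 3 * slice_idx // n_slices)


def aha_segment(theta_deg: np.ndarray, slice_idx: int, n_slices: int,
                rv_insertion_deg: float) -> np.ndarray:
    """AHA 16-segment ring-scheme label for voxel angles on one slice."""
    a = (theta_deg - rv_insertion_deg) % 360.0
    ring = _aha_ring(slice_idx, n_slices)
    if ring == 0:  # apical: 4 segments of 90 deg, centred like the 6-seg rings
        idx = (np.floor(((a + 45.0) % 360.0) / 90.0)).astype(int)
        return 13 + idx  # 13 anterior, 14 septal, 15 inferior, 16 lateral
    base = 1 if ring == 2 else 7
    return base + (np.floor(a / 60.0)).astype(int)


def build_phantom(config: PhantomConfig, timepoint: str | int = 0) -> GroundTruth:
    """Build masks, parcellation and ground-truth maps for one timepoint."""
    tp = (config.timepoints[timepoint] if isinstance(timepoint, int)
          else config.timepoint(timepoint))
    n = config.grid_size
    nz = config.n_slices
    endo_r, epi_r = config.radii_mm()
    ax = (np.arange(n) - (n - 1) / 2.0) * config.pixel_spacing_mm
    X, Y = np.meshgrid(ax, ax)
    R = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X))

    myo = np.zeros((nz, n, n), dtype=bool)
    blood = np.zeros_like(myo)
    infarct = np.zeros_like(myo)
    depth = np.full((nz, n, n), np.nan)
    aha = np.zeros((nz, n, n), dtype=int)
    endo_contours, epi_contours = [], []
    for s in range(nz):
        ring = (R >= endo_r[s]) & (R < epi_r[s])
        myo[s] = ring
        if config.blood_pool:
            blood[s] = R < endo_r[s]
        depth[s][ring] = (R[ring] - endo_r[s]) / (epi_r[s] - endo_r[s]) * 100.0
        aha[s][ring] = aha_segment(theta[ring], s, nz, config.rv_insertion_angle_deg)
        if config.infarct_sector_deg is not None:
            lo, hi = config.infarct_slices
            if lo <= s < hi:
                infarct[s] = ring & _in_sector(theta, config.infarct_sector_deg)
        endo_contours.append(_circle_contour(endo_r[s]))
        epi_contours.append(_circle_contour(epi_r[s]))
    remote = myo & ~infarct

    frames = local_coordinate_frame(myo, endo_contours, epi_contours,
                                    config.pixel_spacing_mm)
    # use the analytic depth for the ground truth (identical to the frame
    # computation for circular contours up to interpolation error)
    ha = np.full((nz, n, n), np.nan)
    ha[myo] = tp.ha_endo_deg + depth[myo] / 100.0 * (tp.ha_epi_deg - tp.ha_endo_deg)

    def _fill(attr: str) -> np.ndarray:
        out = np.zeros((nz, n, n))
        out[remote] = getattr(tp.remote, attr)
        if tp.infarct is not None:
            out[infarct] = getattr(tp.infarct, attr)
        out[blood] = getattr(tp.blood, attr)
        return out

    scar = np.zeros((nz, n, n), dtype=bool)
    if tp.infarct is not None and tp.infarct.scar:
        scar[infarct] = True

    return GroundTruth(
        config=config, timepoint=tp,
        myocardium=myo, blood=blood, infarct=infarct, remote=remote, aha=aha,
        t1_native=_fill("t1_native_ms"), t1_post=_fill("t1_post_ms"),
        t2=_fill("t2_ms"), md=_fill("md_mm2s"), fa=_fill("fa"),
        ha=ha, scar=scar, depth_pct=depth, frames=frames,
        z_mm=config.z_positions_mm(),
        endo_radius_mm=endo_r, epi_radius_mm=epi_r,
        endo_contours=endo_contours, epi_contours=epi_contours,
    )


def make_tensor_field(gt: GroundTruth, include_blood: bool = True) -> TensorField:
    """Axially symmetric tensors realising the prescribed MD, FA and HA.

    Eigenvalues lam1 = MD (1 + 2 delta), lam2 = lam3 = MD (1 - delta) with
    delta = FA / sqrt(3 - 2 FA^2); the primary eigenvector lies in the
    circumferential-longitudinal surface at the prescribed helix angle.
    Recomputing MD and FA from the tensor returns the inputs exactly.
    """
    mask = gt.myocardium | (gt.blood if include_blood else False)
    fa = gt.fa[mask]
    if np.any(fa >= 1):
        raise ValueError("FA >= 1 would require a non-positive secondary eigenvalue")
    md = gt.md[mask]
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam1 = md * (1.0 + 2.0 * delta)
    lam2 = md * (1.0 - delta)

    ha_rad = np.radians(np.where(np.isfinite(gt.ha), gt.ha, 0.0))[mask]
    c, l = gt.frames.c_hat[mask], gt.frames.l_hat[mask]
    e1 = np.cos(ha_rad)[:, None] * c + np.sin(ha_rad)[:, None] * l
    # blood voxels have no frame; their FA is ~0, direction irrelevant
    no_frame = np.linalg.norm(e1, axis=1) < 0.5
    e1[no_frame] = np.array([1.0, 0.0, 0.0])

    D = np.zeros(mask.shape + (3, 3))
    T = (lam2[:, None, None] * np.eye(3)[None]
         + (lam1 - lam2)[:, None, None] * np.einsum("vi,vj->vij", e1, e1))
    D[mask] = T
    return TensorField(tensor=D, mask=mask)


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return signal
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def simulate_dwi(
    tensors: TensorField,
    protocol: Optional[DiffusionProtocol] = None,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_spacing_mm: float = 2.0,
    slice_spacing_mm: float = 8.0,
) -> ImageSeries:
    """Forward DWI: signal = s0 exp(-b g^T D g), Rician noise, averaged repetitions.

    ``protocol.averages`` independent noisy repetitions are simulated and their
    magnitudes averaged, mirroring signal averaging on the scanner.
    ``noise_sigma`` is the per-repetition Gaussian channel SD in signal units.
    """
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(seed)
    g = protocol.bvecs
    b = protocol.bvals
    quad = np.einsum("ni,...ij,nj->n...", g, tensors.tensor, g)  # (n, *vol)
    clean = s0 * np.exp(-b.reshape(-1, *([1] * (quad.ndim - 1))) * quad)
    clean = np.where(tensors.mask[None], clean, 0.0)
    if noise_sigma > 0:
        acc = np.zeros_like(clean)
        for _ in range(protocol.averages):
            acc += _rician(clean, noise_sigma, rng)
        data = acc / protocol.averages
    else:
        data = clean
    meta = pd.DataFrame({
        "bval": b, "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2],
    })
    return ImageSeries(data=data, frame_meta=meta,
                       pixel_spacing_mm=pixel_spacing_mm,
                       slice_spacing_mm=slice_spacing_mm, modality="dwi",
                       extra={"s0": s0, "averages": protocol.averages})


def default_inversion_times(post_contrast: bool = False) -> np.ndarray:
    """Inversion delays (ms): 11 pre-contrast, 13 denser/shorter post-contrast."""
    if post_contrast:
        return np.r_[np.geomspace(80.0, 600.0, 8), np.linspace(800.0, 2000.0, 5)]
    return np.r_[100.0, 180.0, 260.0, np.linspace(400.0, 4000.0, 8)]


def simulate_molli(
    t1_map: np.ndarray,
    inversion_times_ms: Optional[Sequence[float]] = None,
    mask: Optional[np.ndarray] = None,
    a: float = 1000.0,
    inversion_efficiency: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_spacing_mm: float = 2.0,
    slice_spacing_mm: float = 8.0,
) -> ImageSeries:
    """Magnitude inversion-recovery series |A - B exp(-TI/T1*)|.

    With perfect inversion B = 2A and the Look-Locker identity makes T1* = T1,
    so the map is sampled directly; ``inversion_efficiency`` < 1 lowers B.
    Gaussian noise is added to both quadrature channels before the magnitude.
    """
    tis = np.asarray(default_inversion_times() if inversion_times_ms is None
                     else inversion_times_ms, dtype=float)
    if tis.size < 4:
        raise ValueError("need >= 4 inversion times for an identifiable fit downstream")
    t1 = np.asarray(t1_map, dtype=float)
    m = np.ones(t1.shape, dtype=bool) if mask is None else mask.astype(bool)
    rng = np.random.default_rng(seed)
    b = a * (1.0 + inversion_efficiency)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = a - b * np.exp(-tis.reshape(-1, *([1] * t1.ndim)) / t1[None])
    sig = np.where(m[None] & (t1[None] > 0), sig, 0.0)
    if noise_sigma > 0:
        sig = _rician(sig, noise_sigma, rng)
    else:
        sig = np.abs(sig)
    meta = pd.DataFrame({"ti_ms": tis})
    return ImageSeries(data=sig, frame_meta=meta,
                       pixel_spacing_mm=pixel_spacing_mm,
                       slice_spacing_mm=slice_spacing_mm, modality="molli",
                       extra={"a": a, "inversion_efficiency": inversion_efficiency})


def default_echo_times(n_echoes: int = 9, delta_te_ms: float = 8.8) -> np.ndarray:
    """Multi-echo T2 sampling: n echoes at multiples of delta TE (8.8 ms)."""
    return delta_te_ms * np.arange(1, n_echoes + 1)


def simulate_multiecho(
    t2_map: np.ndarray,
    echo_times_ms: Optional[Sequence[float]] = None,
    mask: Optional[np.ndarray] = None,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_spacing_mm: float = 2.0,
    slice_spacing_mm: float = 10.0,
) -> ImageSeries:
    """Mono-exponential decay S0 exp(-TE/T2) with Rician noise."""
    tes = np.asarray(default_echo_times() if echo_times_ms is None
                     else echo_times_ms, dtype=float)
    if np.any(tes <= 0):
        raise ValueError("echo times must be positive")
    t2 = np.asarray(t2_map, dtype=float)
    m = np.ones(t2.shape, dtype=bool) if mask is None else mask.astype(bool)
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = s0 * np.exp(-tes.reshape(-1, *([1] * t2.ndim)) / t2[None])
    sig = np.where(m[None] & (t2[None] > 0), sig, 0.0)
    if noise_sigma > 0:
        sig = _rician(sig, noise_sigma, rng)
    meta = pd.DataFrame({"te_ms": tes})
    return ImageSeries(data=sig, frame_meta=meta,
                       pixel_spacing_mm=pixel_spacing_mm,
                       slice_spacing_mm=slice_spacing_mm, modality="t2me",
                       extra={"s0": s0})


def simulate_lge(
    gt: GroundTruth,
    remote_mean: float = 100.0,
    remote_sd: float = 10.0,
    scar_contrast: float = 15.0,
    blood_mean: Optional[float] = None,
    background_mean: float = 20.0,
    seed: int = 0,
) -> ImageSeries:
    """Inversion-recovery LGE with nulled remote myocardium and enhanced scar.

    ``scar_contrast`` is the scar-mean elevation in units of the remote SD
    (default 15, well above the 5SD segmentation threshold).  Blood defaults to
    a bright pool midway between remote and scar.
    """
    if remote_sd <= 0:
        raise ValueError("remote_sd must be positive")
    rng = np.random.default_rng(seed)
    shape = gt.myocardium.shape
    img = rng.normal(background_mean, remote_sd, shape)
    myo_noise = rng.normal(0.0, remote_sd, shape)
    img = np.where(gt.myocardium, remote_mean + myo_noise, img)
    img = np.where(gt.scar, remote_mean + scar_contrast * remote_sd + myo_noise, img)
    if blood_mean is None:
        blood_mean = remote_mean + 0.5 * scar_contrast * remote_sd
    img = np.where(gt.blood, blood_mean + myo_noise, img)
    meta = pd.DataFrame({"frame": [0]})
    return ImageSeries(data=img[None], frame_meta=meta,
                       pixel_spacing_mm=gt.config.pixel_spacing_mm,
                       slice_spacing_mm=gt.config.slice_spacing_mm,
                       modality="lge",
                       extra={"remote_mean": remote_mean, "remote_sd": remote_sd,
                              "scar_contrast": scar_contrast})


def contraction_activation(n_phases: int, peak_fraction: float) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 activation over the cycle, peaking at ``peak_fraction``.

    Renormalised so the maximum over the discrete phase grid is exactly 1;
    the prescribed peak deformation is then attained at some sampled phase.
    """
    if n_phases < 2:
        raise ValueError("need >= 2 phases")
    f = np.arange(n_phases) / (n_phases - 1)
    g = np.where(f <= peak_fraction,
                 f / (2 * peak_fraction),
                 0.5 + (f - peak_fraction) / (2 * (1 - peak_fraction)))
    w = np.sin(np.pi * g)
    return w / w.max()


def simulate_contour_motion(
    gt: GroundTruth,
    torsion_slope_deg_per_mm: Optional[float] = None,
    strain_params: Optional[dict] = None,
    phases: int = 26,
    n_points: int = 72,
) -> TrackedContours:
    """Tracked endo/mid/epi contours and long-axis landmarks over the cycle.

    Slice s at phase t rotates by ``torsion_slope * z_s * w(t)`` where w is the
    contraction activation; the mid-wall radius scales with the prescribed
    global circumferential strain, wall thickness with the radial strain, and
    the long-axis landmark length with the longitudinal strain, so the
    downstream contour-strain estimates recover the prescription exactly at
    zero noise.
    """
    tp = gt.timepoint
    slope = (tp.torsion_slope_deg_per_mm if torsion_slope_deg_per_mm is None
             else torsion_slope_deg_per_mm)
    sp = {"grs_pct": tp.grs_pct, "gcs_pct": tp.gcs_pct, "gls_pct": tp.gls_pct}
    if strain_params:
        sp.update(strain_params)
    w = contraction_activation(phases, gt.config.peak_contraction_fraction)

    nz = gt.config.n_slices
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    unit = np.column_stack([np.cos(th), np.sin(th)])  # (n_points, 2)
    mid0 = (gt.endo_radius_mm + gt.epi_radius_mm) / 2.0
    wall0 = gt.epi_radius_mm - gt.endo_radius_mm

    def ring(radius: np.ndarray, rot_deg: np.ndarray, z: np.ndarray) -> np.ndarray:
        # radius, rot_deg, z: (n_phases, nz); returns (n_phases, nz, n_points, 3)
        ang = th[None, None, :] + np.radians(rot_deg)[..., None]
        x = radius[..., None] * np.cos(ang)
        y = radius[..., None] * np.sin(ang)
        zz = np.broadcast_to(z[..., None], x.shape)
        return np.stack([x, y, zz], axis=-1)

    rot = slope * gt.z_mm[None, :] * w[:, None]  # (phases, nz)
    mid_r = mid0[None, :] * (1.0 + sp["gcs_pct"] / 100.0 * w[:, None])
    wall = wall0[None, :] * (1.0 + sp["grs_pct"] / 100.0 * w[:, None])
    endo_r = mid_r - wall / 2.0
    epi_r = mid_r + wall / 2.0
    if np.any(endo_r <= 0):
        raise ValueError("prescribed strains collapse the endocardial contour")
    z = np.broadcast_to(gt.z_mm[None, :], rot.shape)
    mid = ring(mid_r, rot, z)
    endo = ring(endo_r, rot, z)
    epi = ring(epi_r, rot, z)

    # long-axis landmark polyline along the LV axis, length scaling with GLS
    l0 = max(gt.z_mm.max() - gt.z_mm.min(), gt.config.slice_spacing_mm)
    lscale = 1.0 + sp["gls_pct"] / 100.0 * w  # (phases,)
    lm_z = np.linspace(0.0, l0, 5)[None, :] * lscale[:, None]
    landmarks = np.stack([np.zeros_like(lm_z), np.zeros_like(lm_z), lm_z], axis=-1)

    return TrackedContours(mid=mid, z0_mm=gt.z_mm.copy(), endo=endo, epi=epi,
                           landmarks=landmarks)


def simulate_cavity_masks(gt: GroundTruth, tc: TrackedContours) -> np.ndarray:
    """Rasterise the endocardial contours into per-phase cavity masks."""
    if tc.endo is None:
        raise ValueError("cavity masks need endocardial contours")
    n = gt.config.grid_size
    px = gt.config.pixel_spacing_mm
    nph, nz = tc.endo.shape[:2]
    masks = np.zeros((nph, nz, n, n), dtype=bool)
    for t in range(nph):
        for s in range(nz):
            pts = tc.endo[t, s, :, :2]
            rows = pts[:, 1] / px + (n - 1) / 2.0
            cols = pts[:, 0] / px + (n - 1) / 2.0
            rr, cc = _sk_polygon(rows, cols, shape=(n, n))
            masks[t, s, rr, cc] = True
    return masks
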