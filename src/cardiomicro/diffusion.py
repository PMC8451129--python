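"""Cardiac diffusion-tensor analysis.

Fits the diffusion tensor to multi-shell DWI by weighted linear least squares
on the log-signal, derives mean diffusivity (MD) and fractional anisotropy
(FA), builds per-voxel left-ventricular local frames (radial, circumferential,
longitudinal), computes helix-angle (HA) maps by projecting the primary
eigenvector onto the circumferential-longitudinal surface, and regresses HA
against normalised transmural depth in the septal segments to obtain the
transmural HA gradient in degrees per percent wall depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .containers import ImageSeries

__all__ = [
    "DiffusionProtocol",
    "TensorField",
    "LVFrameField",
    "HAGradientResult",
    "default_protocol",
    "fit_diffusion_tensor",
    "tensor_metrics",
    "local_coordinate_frame",
    "helix_angle_map",
    "transmural_ha_gradient",
]


@dataclass
class DiffusionProtocol:
    """Diffusion encoding scheme: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3), unit norm
    averages: int = 1

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        norms = np.linalg.norm(self.bvecs, axis=1)
        if not np.allclose(norms[self.bvals > 0], 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit vectors")
        self.validate_design()

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    def design_matrix(self) -> np.ndarray:
        """Rows (1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz)."""
        b = self.bvals
        g = self.bvecs
        return np.column_stack([
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ])

    def validate_design(self) -> None:
        if np.linalg.matrix_rank(self.design_matrix()) < 7:
            raise ValueError(
                "rank-deficient diffusion protocol: need >= 6 unique directions "
                "over >= 2 b-shells to identify ln S0 and the 6 tensor elements"
            )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, well-spread unit directions on the upper hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = i / n  # avoid the equatorial degeneracy at z=0
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_protocol(averages: int = 8) -> DiffusionProtocol:
    """The 18-direction 3-shell in-vivo scheme: 3 @ b100, 3 @ b200, 12 @ b450."""
    d100 = np.eye(3)
    d200 = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]]) / np.sqrt(2.0)
    d450 = _fibonacci_hemisphere(12)
    bvals = np.r_[np.full(3, 100.0), np.full(3, 200.0), np.full(12, 450.0)]
    bvecs = np.vstack([d100, d200, d450])
    return DiffusionProtocol(bvals=bvals, bvecs=bvecs, averages=averages)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with its eigensystem.

    ``tensor`` has shape ``(*vol_shape, 3, 3)``; eigenvalues are sorted in
    descending order; ``evecs[..., :, k]`` is the eigenvector of ``evals[..., k]``.
    """

    tensor: np.ndarray
    mask: np.ndarray
    evals: np.ndarray = field(default=None)  # type: ignore[assignment]
    evecs: np.ndarray = field(default=None)  # type: ignore[assignment]
    flagged: Optional[np.ndarray] = None  # voxels with clipped signals / negative evals

    def __post_init__(self) -> None:
        if self.evals is None:
            self._eigensystem()

    def _eigensystem(self) -> None:
        vals = np.zeros(self.mask.shape + (3,))
        vecs = np.zeros(self.mask.shape + (3, 3))
        m = self.mask.astype(bool)
        if m.any():
            w, v = np.linalg.eigh(self.tensor[m])
            order = np.argsort(w, axis=-1)[:, ::-1]
            w = np.take_along_axis(w, order, axis=-1)
            v = np.take_along_axis(v, order[:, None, :], axis=-1)
            vals[m] = w
            vecs[m] = v
        self.evals = vals
        self.evecs = vecs

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., :, 0]


def fit_diffusion_tensor(
    dwi: ImageSeries | np.ndarray,
    protocol: DiffusionProtocol,
    mask: np.ndarray,
    signal_floor: float = 1e-6,
) -> TensorField:
    """Weighted linear least-squares tensor fit on the log-signal.

    Weights are the squared signals (the standard first-order variance
    correction for log-transformed Rician/Gaussian magnitude data).  Signals at
    or below ``signal_floor`` are clipped and the voxel flagged.
    """
    data = dwi.data if isinstance(dwi, ImageSeries) else np.asarray(dwi, dtype=float)
    if data.shape[0] != protocol.n_volumes:
        raise ValueError("DWI frame count does not match protocol")
    X = protocol.design_matrix()  # (n, 7)
    m = mask.astype(bool)
    sig = data[:, m].T  # (nvox, n)
    flagged_low = (sig <= signal_floor).any(axis=1)
    sig = np.clip(sig, signal_floor, None)
    y = np.log(sig)
    w = sig**2
    # batched weighted normal equations
    Xw = X[None, :, :] * w[:, :, None]  # (nvox, n, 7)
    A = np.einsum("vnp,nq->vpq", Xw, X)
    b = np.einsum("vnp,vn->vp", Xw, y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # (nvox, 7)
    D = np.zeros(m.shape + (3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(1, 7))
    T = np.empty((beta.shape[0], 3, 3))
    T[:, 0, 0] = dxx
    T[:, 1, 1] = dyy
    T[:, 2, 2] = dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz
    D[m] = T
    flagged = np.zeros(m.shape, dtype=bool)
    flagged[m] = flagged_low
    return TensorField(tensor=D, mask=m, flagged=flagged)


def tensor_metrics(tf: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """MD and FA maps from the eigenvalues.

    MD = trace/3.  FA = sqrt(1/2) * sqrt(sum of squared eigenvalue differences)
    / sqrt(sum of squared eigenvalues); an all-zero tensor has FA = 0, and FA is
    clipped to [0, 1] (noise can produce negative eigenvalues, which are
    flagged on the field).
    """
    lam = tf.evals
    md = lam.mean(axis=-1)
    num = ((lam[..., 0] - lam[..., 1]) ** 2
           + (lam[..., 1] - lam[..., 2]) ** 2
           + (lam[..., 2] - lam[..., 0]) ** 2)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    neg = (lam < 0).any(axis=-1) & tf.mask
    if neg.any():
        tf.flagged = neg if tf.flagged is None else (tf.flagged | neg)
    md = np.where(tf.mask, md, 0.0)
    fa = np.where(tf.mask, fa, 0.0)
    return md, fa


@dataclass
class LVFrameField:
    """Per-voxel LV local frame and normalised transmural depth.

    ``r_hat`` points outward from the slice centroid, ``l_hat`` along the slice
    normal (apex -> base), ``c_hat = l_hat x r_hat`` (counterclockwise viewed
    from base); the triad is right-handed orthonormal.  ``depth_pct`` runs from
    0 at the endocardial border to 100 at the epicardial border.
    """

    r_hat: np.ndarray
    c_hat: np.ndarray
    l_hat: np.ndarray
    depth_pct: np.ndarray
    valid: np.ndarray


def _contour_radius_at(contour: np.ndarray, center: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Radius of a closed contour at query angles, by angular interpolation."""
    d = contour - center[None, :]
    ang = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    ang_s, rad_s = ang[order], rad[order]
    # wrap for periodic interpolation
    ang_ext = np.r_[ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi]
    rad_ext = np.r_[rad_s, rad_s, rad_s]
    return np.interp(theta, ang_ext, rad_ext)


def local_coordinate_frame(
    mask: np.ndarray,
    endo_contours: Sequence[np.ndarray],
    epi_contours: Sequence[np.ndarray],
    pixel_spacing_mm: float,
) -> LVFrameField:
    """Build radial/circumferential/longitudinal unit vectors and depth.

    Contours are per-slice closed point lists (n, 2) in mm, in the same in-plane
    coordinates as the voxel grid (origin at the grid centre).  Depth is the
    normalised position of the voxel along its centroid ray between the endo
    and epi contour crossings.
    """
    nz, ny, nx = mask.shape
    if len(endo_contours) != nz or len(epi_contours) != nz:
        raise ValueError("need one endo and one epi contour per slice")
    r_hat = np.zeros(mask.shape + (3,))
    c_hat = np.zeros(mask.shape + (3,))
    l_hat = np.zeros(mask.shape + (3,))
    depth = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing_mm
    X, Y = np.meshgrid(xs, ys)
    for s in range(nz):
        endo, epi = np.asarray(endo_contours[s]), np.asarray(epi_contours[s])
        for c in (endo, epi):
            if c.ndim != 2 or c.shape[0] < 3:
                raise ValueError("contours must be closed point lists of >= 3 points")
        m = mask[s]
        if not m.any():
            continue
        center = epi.mean(axis=0)
        dx, dy = X[m] - center[0], Y[m] - center[1]
        theta = np.arctan2(dy, dx)
        r = np.hypot(dx, dy)
        r_endo = _contour_radius_at(endo, center, theta)
        r_epi = _contour_radius_at(epi, center, theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            dep = (r - r_endo) / (r_epi - r_endo)
        ok = np.isfinite(dep) & (r > 0)
        depth_s = np.full(m.sum(), np.nan)
        depth_s[ok] = np.clip(dep[ok], 0.0, 1.0) * 100.0
        depth[s][m] = depth_s
        ct, st = np.cos(theta), np.sin(theta)
        r_hat[s][m] = np.column_stack([ct, st, np.zeros_like(ct)])
        # l_hat along +z (apex -> base); c_hat = l_hat x r_hat
        l_hat[s][m] = np.array([0.0, 0.0, 1.0])
        c_hat[s][m] = np.column_stack([-st, ct, np.zeros_like(ct)])
        v = np.zeros(m.sum(), dtype=bool)
        v[ok] = True
        valid[s][m] = v
    return LVFrameField(r_hat=r_hat, c_hat=c_hat, l_hat=l_hat, depth_pct=depth, valid=valid)


def helix_angle_map(
    tf: TensorField,
    frames: LVFrameField,
    min_projection_norm: float = 0.2,
) -> np.ndarray:
    """Helix angle (degrees) of the primary eigenvector, NaN where invalid.

    The eigenvector is projected onto the circumferential-longitudinal surface
    (radial component removed).  Eigenvectors are sign-ambiguous, so e1 is
    flipped to make the circumferential component non-negative; at the +-90 deg
    boundary (circumferential component ~ 0) the tie is broken by flipping to a
    non-negative longitudinal component.  Voxels whose e1 is dominantly radial
    (projection norm below ``min_projection_norm``) are masked invalid.
    """
    e1 = tf.e1
    pr = np.einsum("...i,...i->...", e1, frames.r_hat)
    p = e1 - pr[..., None] * frames.r_hat
    pn = np.linalg.norm(p, axis=-1)
    pc = np.einsum("...i,...i->...", p, frames.c_hat)
    pl = np.einsum("...i,...i->...", p, frames.l_hat)
    # antipodal symmetry: enforce pc >= 0; break pc ~ 0 ties toward pl >= 0
    flip = (pc < 0) | ((np.abs(pc) < 1e-12) & (pl < 0))
    sgn = np.where(flip, -1.0, 1.0)
    pc, pl = pc * sgn, pl * sgn
    ha = np.degrees(np.arctan2(pl, pc))
    bad = (~tf.mask) | (~frames.valid) | (pn < min_projection_norm)
    ha = np.where(bad, np.nan, ha)
    return ha


@dataclass
class HAGradientResult:
    slope_deg_per_pct: float
    intercept_deg: float
    r_squared: float
    n_voxels: int


def transmural_ha_gradient(
    ha_map: np.ndarray,
    frames: LVFrameField,
    segment_labels: np.ndarray,
    segments: Sequence[int] = (8, 9),
    min_voxels: int = 20,
) -> HAGradientResult:
    """OLS slope of helix angle (deg) against transmural depth (%) in the septum.

    The gradient is evaluated in the remote septal segments only (AHA segments
    8 and 9 by default): the infarcted lateral wall is too thin for a reliable
    transmural regression.
    """
    sel = np.isin(segment_labels, list(segments)) & np.isfinite(ha_map) & frames.valid
    n = int(sel.sum())
    if n < min_voxels:
        raise ValueError(
            f"insufficient valid voxels ({n} < {min_voxels}) in AHA segments "
            f"{tuple(segments)} for the transmural HA regression"
        )
    x = frames.depth_pct[sel]
    y = ha_map[sel]
    res = _sps.linregress(x, y)
    return HAGradientResult(
        slope_deg_per_pct=float(res.slope),
        intercept_deg=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_voxels=n,
    )
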