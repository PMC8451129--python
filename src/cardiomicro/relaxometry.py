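"""T1 (inversion-recovery / MOLLI), T2 (multi-echo) and ECV mapping.

The MOLLI magnitude signal is |A - B exp(-TI/T1*)| with the Look-Locker
correction T1 = T1* (B/A - 1).  Magnitude data lose the sign of pre-null
samples; the fit restores polarity by trying every "first k samples inverted"
hypothesis and keeping the lowest-residual solution.  For fixed T1* the signed
model is linear in (A, B), so the fit reduces to a 1-D search over T1*: a
coarse log-spaced grid followed by vectorised golden-section refinement.  This
is exact on noiseless data and has no per-voxel Python-level optimiser loop.

T2 mapping uses a weighted log-linear mono-exponential fit (weights = squared
signal), with an optional constant-offset variant.

ECV = (1 - Hct) * (dR1_myo / dR1_blood), with dR1 = 1/T1_post - 1/T1_pre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ImageSeries

__all__ = ["T1FitResult", "ECVMap", "fit_t1_map", "fit_t2_map", "compute_ecv_map"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class T1FitResult:
    """Per-voxel three-parameter inversion-recovery fit."""

    a: np.ndarray
    b: np.ndarray
    t1_star_ms: np.ndarray
    t1_ms: np.ndarray
    residual: np.ndarray
    valid: np.ndarray


def _signed_lstsq(signed: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form LS of signed ~ A - B*E per voxel; returns (A, B, rss).

    ``signed``: (nvox, nt); ``E``: (nvox, nt) or (nt,).
    """
    E = np.broadcast_to(E, signed.shape)
    nt = signed.shape[1]
    se = E.sum(axis=1)
    see = (E * E).sum(axis=1)
    sy = signed.sum(axis=1)
    sye = (signed * E).sum(axis=1)
    det = nt * see - se**2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    # solve [[nt, -se], [-se, see]] [A, -B]... expanded directly:
    a = (see * sy - se * sye) / det
    b = -(nt * sye - se * sy) / det  # model A - B E  =>  coefficient of E is -B
    resid = signed - (a[:, None] - b[:, None] * E)
    return a, b, (resid**2).sum(axis=1)


def _rss_for_t1star(signed: np.ndarray, tis: np.ndarray, t1s: np.ndarray) -> np.ndarray:
    E = np.exp(-tis[None, :] / t1s[:, None])
    _, _, rss = _signed_lstsq(signed, E)
    return rss


def fit_t1_map(
    series: ImageSeries,
    mask: np.ndarray,
    t1_star_bounds_ms: tuple[float, float] = (20.0, 8000.0),
    n_grid: int = 160,
    n_refine: int = 90,
) -> T1FitResult:
    """Fit T1 per voxel from a magnitude inversion-recovery series.

    Requires >= 4 distinct inversion times.  Voxels where the fit is degenerate
    (A <= 0 or B <= 0 or non-finite) are flagged invalid and should be excluded
    from ROI means.
    """
    tis = np.asarray(series.frame_meta["ti_ms"], dtype=float)
    if np.unique(tis).size < 4:
        raise ValueError("T1 fit needs >= 4 distinct inversion times")
    order = np.argsort(tis)
    tis = tis[order]
    m = mask.astype(bool)
    sig = series.data[order][:, m].T  # (nvox, nt)
    nvox, nt = sig.shape
    lo, hi = t1_star_bounds_ms
    grid = np.geomspace(lo, hi, n_grid)

    # polarity hypotheses: first k samples (sorted by TI) inverted
    max_flip = nt - 2
    best_rss = np.full(nvox, np.inf)
    best_k = np.zeros(nvox, dtype=int)
    best_j = np.zeros(nvox, dtype=int)
    E_grid = np.exp(-tis[None, :] / grid[:, None])  # (ng, nt)
    for k in range(max_flip + 1):
        signed = sig.copy()
        signed[:, :k] *= -1.0
        for j, E in enumerate(E_grid):
            _, _, rss = _signed_lstsq(signed, E)
            better = rss < best_rss
            best_rss[better] = rss[better]
            best_k[better] = k
            best_j[better] = j

    # golden-section refinement of T1* per voxel, polarity fixed
    signed = sig * np.where(np.arange(nt)[None, :] < best_k[:, None], -1.0, 1.0)
    jlo = np.clip(best_j - 1, 0, n_grid - 1)
    jhi = np.clip(best_j + 1, 0, n_grid - 1)
    a_br = grid[jlo]
    b_br = grid[jhi]
    x1 = b_br - _GOLDEN * (b_br - a_br)
    x2 = a_br + _GOLDEN * (b_br - a_br)
    f1 = _rss_for_t1star(signed, tis, x1)
    f2 = _rss_for_t1star(signed, tis, x2)
    for _ in range(n_refine):
        take1 = f1 < f2  # minimum in [a, x2]
        b_br = np.where(take1, x2, b_br)
        a_br = np.where(take1, a_br, x1)
        x1_new = b_br - _GOLDEN * (b_br - a_br)
        x2_new = a_br + _GOLDEN * (b_br - a_br)
        probe = np.where(take1, x1_new, x2_new)
        f_probe = _rss_for_t1star(signed, tis, probe)
        # take1: old x1 becomes x2; else old x2 becomes x1
        f2_next = np.where(take1, f1, f_probe)
        f1_next = np.where(take1, f_probe, f2)
        x1, x2, f1, f2 = x1_new, x2_new, f1_next, f2_next
    t1_star = (a_br + b_br) / 2.0
    E = np.exp(-tis[None, :] / t1_star[:, None])
    a, b, rss = _signed_lstsq(signed, E)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = t1_star * (b / a - 1.0)
    ok = np.isfinite(t1) & (a > 0) & (b > 0) & (t1 > 0)

    def _full(v: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(m.shape, fill)
        out[m] = v
        return out

    return T1FitResult(
        a=_full(a), b=_full(b), t1_star_ms=_full(t1_star),
        t1_ms=_full(np.where(ok, t1, np.nan)),
        residual=_full(np.sqrt(rss)),
        valid=_full(ok, 0.0).astype(bool) & m,
    )


def fit_t2_map(
    series: ImageSeries,
    mask: np.ndarray,
    min_echoes: int = 3,
    with_offset: bool = False,
) -> np.ndarray:
    """Mono-exponential T2 fit per voxel; NaN where invalid.

    Weighted log-linear least squares with weights = squared signal; samples
    with non-positive signal are excluded per voxel, and voxels with fewer than
    ``min_echoes`` usable echoes are invalid.  ``with_offset=True`` switches to
    a 3-parameter nonlinear fit S0*exp(-TE/T2)+C (slower; per-voxel).
    """
    tes = np.asarray(series.frame_meta["te_ms"], dtype=float)
    if tes.size < min_echoes:
        raise ValueError(f"T2 fit needs >= {min_echoes} echoes")
    m = mask.astype(bool)
    sig = series.data[:, m].T  # (nvox, nt)
    if with_offset:
        from scipy.optimize import curve_fit

        t2 = np.full(sig.shape[0], np.nan)
        for i, s in enumerate(sig):
            good = s > 0
            if good.sum() < max(min_echoes, 3):
                continue
            try:
                p0 = (s[good].max(), 50.0, 0.0)
                popt, _ = curve_fit(
                    lambda te, s0, t2_, c: s0 * np.exp(-te / t2_) + c,
                    tes[good], s[good], p0=p0, maxfev=2000,
                )
                if popt[1] > 0:
                    t2[i] = popt[1]
            except RuntimeError:
                pass
    else:
        good = sig > 0
        w = np.where(good, sig**2, 0.0)
        y = np.where(good, np.log(np.where(good, sig, 1.0)), 0.0)
        # weighted linear fit y = ln S0 - TE/T2 per voxel
        sw = w.sum(axis=1)
        swx = (w * tes).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swxx = (w * tes**2).sum(axis=1)
        swxy = (w * tes * y).sum(axis=1)
        det = sw * swxx - swx**2
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (sw * swxy - swx * swy) / det
            t2 = -1.0 / slope
        t2 = np.where((good.sum(axis=1) >= min_echoes) & (t2 > 0), t2, np.nan)
    out = np.full(m.shape, np.nan)
    out[m] = t2
    return out


@dataclass
class ECVMap:
    """Extracellular-volume-fraction map with the inputs it was computed from."""

    ecv: np.ndarray  # fraction in [0, 1] after clipping; NaN where inputs invalid
    hematocrit: float
    blood_t1_pre_ms: float
    blood_t1_post_ms: float
    n_clipped: int = 0
    extra: dict = field(default_factory=dict)


def compute_ecv_map(
    t1_pre: np.ndarray,
    t1_post: np.ndarray,
    blood_t1_pre_ms: float,
    blood_t1_post_ms: float,
    hematocrit: float,
    mask: Optional[np.ndarray] = None,
) -> ECVMap:
    """ECV = (1 - Hct) * dR1_myo / dR1_blood, clipped to [0, 1] with a clip count."""
    if not (0 < hematocrit < 1):
        raise ValueError("hematocrit must lie in (0, 1)")
    dr1_blood = 1.0 / blood_t1_post_ms - 1.0 / blood_t1_pre_ms
    if dr1_blood <= 0:
        raise ValueError("blood T1 must decrease after contrast (dR1_blood > 0)")
    t1_pre = np.asarray(t1_pre, dtype=float)
    t1_post = np.asarray(t1_post, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ecv = (1.0 - hematocrit) * (1.0 / t1_post - 1.0 / t1_pre) / dr1_blood
    bad = ~np.isfinite(ecv) | (t1_pre <= 0) | (t1_post <= 0)
    if mask is not None:
        bad |= ~mask.astype(bool)
    n_clip = int(np.sum(((ecv < 0) | (ecv > 1)) & ~bad))
    ecv = np.clip(ecv, 0.0, 1.0)
    ecv = np.where(bad, np.nan, ecv)
    return ECVMap(
        ecv=ecv, hematocrit=hematocrit,
        blood_t1_pre_ms=blood_t1_pre_ms, blood_t1_post_ms=blood_t1_post_ms,
        n_clipped=n_clip,
    )
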