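"""Late-gadolinium-enhancement scar segmentation and infarct mass.

Scar is segmented by intensity thresholding at the remote-tissue mean plus a
multiple (default 5) of the remote-tissue standard deviation; masses follow
from the voxel volume and a myocardial tissue density of 1.05 g/ml, and scar
size is reported as a percentage of total myocardial mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

from .containers import ImageSeries

__all__ = ["ScarResult", "segment_scar_5sd"]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class ScarResult:
    scar_mask: np.ndarray
    threshold: float
    scar_mass_g: float
    myocardial_mass_g: float
    scar_fraction_pct: float
    density_g_per_ml: float
    remote_mean: float
    remote_sd: float
    refined: bool = False


def segment_scar_5sd(
    lge: ImageSeries | np.ndarray,
    myocardium_mask: np.ndarray,
    remote_roi: np.ndarray,
    sd_factor: float = 5.0,
    voxel_volume_ml: float | None = None,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
    largest_component: bool = False,
    min_remote_voxels: int = 10,
) -> ScarResult:
    """Threshold myocardium at mean(remote) + sd_factor * SD(remote).

    ``largest_component=True`` keeps only the largest connected component of
    the supra-threshold mask (an automated stand-in for manual refinement;
    off by default).  The remote ROI must be non-enhanced tissue disjoint from
    the suspected scar.
    """
    if isinstance(lge, ImageSeries):
        img = lge.data[0]
        if voxel_volume_ml is None:
            voxel_volume_ml = lge.voxel_volume_ml
    else:
        img = np.asarray(lge, dtype=float)
        if voxel_volume_ml is None:
            raise ValueError("voxel_volume_ml required when passing a bare array")
    myo = myocardium_mask.astype(bool)
    remote = remote_roi.astype(bool)
    if remote.sum() < min_remote_voxels:
        raise ValueError(
            f"remote ROI has {int(remote.sum())} voxels; need >= {min_remote_voxels} "
            "for a reliable SD estimate"
        )
    mu = float(img[remote].mean())
    sd = float(img[remote].std(ddof=1))
    thr = mu + sd_factor * sd
    scar = myo & (img > thr)
    refined = False
    if largest_component and scar.any():
        lab = _cc_label(scar)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        scar = lab == sizes.argmax()
        refined = True
    scar_mass = float(scar.sum()) * voxel_volume_ml * density_g_per_ml
    total_mass = float(myo.sum()) * voxel_volume_ml * density_g_per_ml
    frac = 100.0 * scar.sum() / myo.sum() if myo.any() else 0.0
    return ScarResult(
        scar_mask=scar, threshold=thr,
        scar_mass_g=scar_mass, myocardial_mass_g=total_mass,
        scar_fraction_pct=float(frac),
        density_g_per_ml=density_g_per_ml,
        remote_mean=mu, remote_sd=sd, refined=refined,
    )
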