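"""Left-ventricular function: volumes, torsion, and simplified global strains.

Volumes use Simpson summation over short-axis cavity masks.  Torsion follows
the tracked-contour convention: the rotation of each slice's mid-mural contour
about its centre axis is regressed against the slice's *initial* longitudinal
position, and the slope (degrees/mm) is the torsion; the peak over the cardiac
cycle is reported at its signed value.  Global strains are geometric contour
strains: circumferential from the mid-wall perimeter, radial from mean wall
thickness, longitudinal from a tracked long-axis landmark polyline — a
deliberately simple, fully transparent alternative to feature-tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrackedContours",
    "FunctionReport",
    "lv_volumes",
    "torsion_from_contours",
    "global_strains",
]


@dataclass
class TrackedContours:
    """Point-corresponded contours per slice and cardiac phase.

    ``mid``/``endo``/``epi`` have shape ``(n_phases, n_slices, n_points, 3)``
    in mm; ``z0_mm`` are the initial (phase-0) longitudinal slice positions;
    ``landmarks`` is an optional ``(n_phases, n_points, 3)`` long-axis polyline
    for longitudinal strain.
    """

    mid: np.ndarray
    z0_mm: np.ndarray
    endo: Optional[np.ndarray] = None
    epi: Optional[np.ndarray] = None
    landmarks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mid = np.asarray(self.mid, dtype=float)
        self.z0_mm = np.asarray(self.z0_mm, dtype=float)
        if self.mid.ndim != 4 or self.mid.shape[-1] != 3:
            raise ValueError("mid must be (n_phases, n_slices, n_points, 3)")
        if self.z0_mm.shape != (self.mid.shape[1],):
            raise ValueError("z0_mm must have one entry per slice")
        if self.mid.shape[0] < 2:
            raise ValueError("need at least 2 phases")

    @property
    def n_phases(self) -> int:
        return self.mid.shape[0]

    @property
    def n_slices(self) -> int:
        return self.mid.shape[1]


@dataclass
class FunctionReport:
    lvedv_ml: float
    lvesv_ml: float
    sv_ml: float
    lvef_pct: float
    ed_phase: int
    es_phase: int
    torsion_deg_per_mm: Optional[np.ndarray] = None
    peak_torsion_deg_per_mm: Optional[float] = None
    grs_pct: Optional[float] = None
    gcs_pct: Optional[float] = None
    gls_pct: Optional[float] = None


def lv_volumes(
    cavity_masks: np.ndarray | Sequence[np.ndarray],
    slice_spacing_mm: float,
    pixel_spacing_mm: float,
) -> FunctionReport:
    """Simpson-summation volumes over phases -> (LVEDV, LVESV, SV, LVEF).

    ``cavity_masks``: boolean array (n_phases, n_slices, ny, nx).  ED is the
    max-volume phase and ES the min-volume phase; SV = LVEDV - LVESV and
    LVEF = 100 SV / LVEDV.
    """
    masks = np.asarray(cavity_masks, dtype=bool)
    if masks.ndim != 4:
        raise ValueError("cavity_masks must be (n_phases, n_slices, ny, nx)")
    counts = masks.sum(axis=(1, 2, 3))
    if counts.max() == 0:
        raise ValueError("cavity empty at every phase")
    vol_ml = counts * pixel_spacing_mm**2 * slice_spacing_mm / 1000.0
    ed = int(np.argmax(vol_ml))
    es = int(np.argmin(vol_ml))
    lvedv, lvesv = float(vol_ml[ed]), float(vol_ml[es])
    sv = lvedv - lvesv
    return FunctionReport(
        lvedv_ml=lvedv, lvesv_ml=lvesv, sv_ml=sv,
        lvef_pct=100.0 * sv / lvedv, ed_phase=ed, es_phase=es,
    )


def _slice_rotations_deg(tc: TrackedContours) -> np.ndarray:
    """Mean angular displacement (deg) of each slice contour vs phase 0.

    Shape (n_phases, n_slices).  Angles are measured about the per-phase slice
    centroid, so the rotation estimate is invariant to translation and to
    radial scaling of the contour.
    """
    pts = tc.mid[..., :2]
    centroids = pts.mean(axis=2, keepdims=True)
    d = pts - centroids
    ang = np.arctan2(d[..., 1], d[..., 0])  # (n_phases, n_slices, n_points)
    delta = ang - ang[0][None]
    delta = (delta + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    # circular mean of the per-point displacements
    rot = np.arctan2(np.sin(delta).mean(axis=-1), np.cos(delta).mean(axis=-1))
    return np.degrees(rot)


def torsion_from_contours(tc: TrackedContours) -> tuple[np.ndarray, float]:
    """Torsion curve (deg/mm per phase) and the signed peak.

    Per phase: least-squares line of slice rotation against the initial
    longitudinal position; the slope is the torsion.  Peak = value of largest
    magnitude over the cycle, keeping its sign.
    """
    z = tc.z0_mm
    if np.ptp(z) == 0:
        raise ValueError("all slices at the same longitudinal position: slope undefined")
    rot = _slice_rotations_deg(tc)  # (n_phases, n_slices)
    zc = z - z.mean()
    slopes = rot @ zc / (zc @ zc)
    peak = float(slopes[np.argmax(np.abs(slopes))])
    return slopes, peak


def _perimeter(points_xy: np.ndarray) -> np.ndarray:
    """Closed-polygon perimeter; points (..., n, 2)."""
    d = np.diff(np.concatenate([points_xy, points_xy[..., :1, :]], axis=-2), axis=-2)
    return np.linalg.norm(d, axis=-1).sum(axis=-1)


def _polygon_area(points_xy: np.ndarray) -> np.ndarray:
    x, y = points_xy[..., 0], points_xy[..., 1]
    x2, y2 = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    return 0.5 * np.abs((x * y2 - x2 * y).sum(axis=-1))


def _mean_radius(points_xy: np.ndarray) -> np.ndarray:
    c = points_xy.mean(axis=-2, keepdims=True)
    return np.linalg.norm(points_xy - c, axis=-1).mean(axis=-1)


def global_strains(tc: TrackedContours) -> dict[str, Optional[float]]:
    """Simplified global strains (%) between end-diastole and end-systole.

    GCS from the mid-wall perimeter, GRS from mean wall thickness (epi minus
    endo mean radius), GLS from the long-axis landmark polyline length.  ED/ES
    phases are identified from cavity area (endo contours) when available,
    otherwise from the mid-wall perimeter.  GLS is None without landmarks.
    """
    if tc.endo is not None:
        areas = _polygon_area(tc.endo[..., :2]).sum(axis=1)
        ed, es = int(np.argmax(areas)), int(np.argmin(areas))
    else:
        per = _perimeter(tc.mid[..., :2]).sum(axis=1)
        ed, es = int(np.argmax(per)), int(np.argmin(per))

    p_mid = _perimeter(tc.mid[..., :2])  # (n_phases, n_slices)
    gcs = float(100.0 * ((p_mid[es] - p_mid[ed]) / p_mid[ed]).mean())

    grs: Optional[float] = None
    if tc.endo is not None and tc.epi is not None:
        w = _mean_radius(tc.epi[..., :2]) - _mean_radius(tc.endo[..., :2])
        grs = float(100.0 * (w[es] - w[ed]).mean() / w[ed].mean())

    gls: Optional[float] = None
    if tc.landmarks is not None:
        seg = np.diff(tc.landmarks, axis=1)
        length = np.linalg.norm(seg, axis=-1).sum(axis=-1)  # (n_phases,)
        gls = float(100.0 * (length[es] - length[ed]) / length[ed])

    return {"grs_pct": grs, "gcs_pct": gcs, "gls_pct": gls,
            "ed_phase": ed, "es_phase": es}
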