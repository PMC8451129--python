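"""Declarative phantom and study configuration.

The phantom is a digital left ventricle: a stack of short-axis annuli with an
inferolateral infarct territory, regional relaxation/diffusion ground truth per
study timepoint, a transmural helix-angle ramp, prescribed torsion and global
strains, and seeded Rician noise.  The default values describe a longitudinal
acute-to-chronic infarction timeline (baseline, day 6, week 5, week 9) in two
cohorts (control and infarct) with group sizes N=4 / N=5.

Units: lengths in mm, times in ms, diffusivities in mm^2/s, angles in degrees,
strains and ECV as stated (percent / fraction).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

TIMEPOINT_LABELS = ("baseline", "day6", "week5", "week9")


class RegionValues(BaseModel):
    """Ground-truth tissue parameters for one region at one timepoint."""

    t1_native_ms: float = Field(gt=0)
    t1_post_ms: float = Field(gt=0)
    t2_ms: float = Field(gt=0)
    md_mm2s: float = Field(gt=0, description="mean diffusivity, mm^2/s")
    fa: float = Field(ge=0, lt=1)
    scar: bool = False


class TimepointSpec(BaseModel):
    """Regional values plus orientation/motion prescription for one timepoint."""

    label: str
    remote: RegionValues
    infarct: Optional[RegionValues] = None
    blood: RegionValues
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0
    torsion_slope_deg_per_mm: float = 0.2
    grs_pct: float = 40.0
    gcs_pct: float = -15.0
    gls_pct: float = -17.0

    @model_validator(mode="after")
    def _check_ha(self) -> "TimepointSpec":
        # right-handed myocytes subendocardially, left-handed subepicardially
        if not (self.ha_endo_deg > 0 > self.ha_epi_deg):
            raise ValueError("require ha_endo > 0 > ha_epi")
        for v in (self.ha_endo_deg, self.ha_epi_deg):
            if abs(v) > 90:
                raise ValueError("helix-angle endpoints must lie in [-90, 90] deg")
        return self


class PhantomConfig(BaseModel):
    """Complete declarative description of the synthetic left ventricle."""

    n_slices: int = Field(default=10, ge=1)
    slice_thickness_mm: float = Field(default=8.0, gt=0)
    slice_gap_mm: float = Field(default=0.0, ge=0)
    pixel_spacing_mm: float = Field(default=2.0, gt=0)
    grid_size: int = Field(default=96, ge=8)
    endo_radius_mm: float = Field(default=20.0, gt=0)
    epi_radius_mm: float = Field(default=30.0, gt=0)
    apex_taper: float = Field(
        default=0.0, ge=0, lt=1,
        description="fractional radius reduction at the apical slice, linear to 0 at base",
    )
    rv_insertion_angle_deg: float = 0.0
    infarct_sector_deg: Optional[tuple[float, float]] = (230.4, 309.6)
    infarct_slices: tuple[int, int] = (4, 9)  # half-open [start, stop)
    blood_pool: bool = True
    hematocrit: float = Field(default=0.33, gt=0, lt=1)
    blood_t1_pre_ms: float = Field(default=1600.0, gt=0)
    blood_t1_post_ms: float = Field(default=280.0, gt=0)
    timepoints: list[TimepointSpec]
    peak_contraction_fraction: float = Field(default=0.35, gt=0, lt=1)
    noise_sigma_frac: float = Field(
        default=1.0 / 30.0, ge=0,
        description="noise SD as a fraction of the reference signal (b=100 shell mean for DWI)",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomConfig":
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ValueError("endo_radius must be smaller than epi_radius")
        half_fov = self.grid_size * self.pixel_spacing_mm / 2.0
        if self.epi_radius_mm >= half_fov:
            raise ValueError(
                f"grid too small: epi radius {self.epi_radius_mm} mm does not fit "
                f"in a {self.grid_size}x{self.grid_size} grid at "
                f"{self.pixel_spacing_mm} mm spacing"
            )
        labels = [tp.label for tp in self.timepoints]
        if len(set(labels)) != len(labels):
            raise ValueError("timepoint labels must be unique")
        return self

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    def timepoint(self, label: str) -> TimepointSpec:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        raise KeyError(f"unknown timepoint {label!r}; have {[t.label for t in self.timepoints]}")

    def radii_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-slice endo/epi radii with the optional apex-base taper (apex first)."""
        n = self.n_slices
        scale = 1.0 - self.apex_taper * (1.0 - np.arange(n) / max(n - 1, 1))
        return self.endo_radius_mm * scale, self.epi_radius_mm * scale

    def z_positions_mm(self) -> np.ndarray:
        """Longitudinal slice positions, apex -> base."""
        return np.arange(self.n_slices) * self.slice_spacing_mm


def t1_post_for_ecv(
    ecv: float,
    t1_native_ms: float,
    blood_t1_pre_ms: float,
    blood_t1_post_ms: float,
    hematocrit: float,
) -> float:
    """Invert the ECV formula: the post-contrast T1 that yields a target ECV.

    ECV = (1 - Hct) * dR1_myo / dR1_blood with dR1 = 1/T1_post - 1/T1_pre.
    """
    dr1_blood = 1.0 / blood_t1_post_ms - 1.0 / blood_t1_pre_ms
    if dr1_blood <= 0:
        raise ValueError("blood T1 must decrease after contrast")
    dr1_myo = ecv * dr1_blood / (1.0 - hematocrit)
    return 1.0 / (dr1_myo + 1.0 / t1_native_ms)


# --------------------------------------------------------------------------
# Default study conditions: the acute-to-chronic infarction timeline.
# Relative changes of the infarct zone vs its pre-infarct (baseline) state:
#   MD  +17% (day 6), +33% (week 5), +29% (week 9)
#   FA  -31% (day 6), -38% (week 5), -36% (week 9)
#   ECV +125% (day 6), +157% (week 5), +146% (week 9)
# Native T1 in the infarct stays within 1099-1128 ms from acute to chronic.
# T2 peaks at 83 ms acutely (remote 61 ms, control 58 ms) and normalises.
# Torsion / strains / HA-gradient endpoints follow the functional summary table.
# --------------------------------------------------------------------------

_HEALTHY = dict(t1_native_ms=960.0, t2_ms=58.0, md_mm2s=1.2e-3, fa=0.45)
_HEALTHY_ECV = 0.24

_INFARCT_TIMELINE = {
    # label: (t1n, t2, md factor, fa factor, ecv factor, scar)
    "day6": (1099.0, 83.0, 1.17, 0.69, 2.25, True),
    "week5": (1128.0, 62.0, 1.33, 0.62, 2.57, True),
    "week9": (1117.0, 59.0, 1.29, 0.64, 2.46, True),
}
_REMOTE_T2 = {"baseline": 58.0, "day6": 61.0, "week5": 60.0, "week9": 59.0}

_MOTION = {
    # cohort -> label -> (ha_endo, ha_epi, torsion, grs, gcs, gls)
    "control": {
        "baseline": (51.0, -51.0, 0.23, 39.0, -16.0, -17.0),
        "day6": (59.5, -59.5, 0.26, 47.0, -18.0, -17.0),
        "week5": (58.5, -58.5, 0.31, 49.0, -18.0, -17.0),
        "week9": (58.0, -58.0, 0.28, 40.0, -17.0, -16.0),
    },
    "infarct": {
        "baseline": (52.0, -52.0, 0.20, 40.0, -15.0, -17.0),
        "day6": (58.0, -58.0, 0.23, 42.0, -14.0, -16.0),
        "week5": (63.0, -63.0, 0.20, 37.0, -15.0, -15.0),
        "week9": (63.0, -63.0, 0.21, 38.0, -14.0, -14.0),
    },
}

_BLOOD = dict(t2_ms=250.0, md_mm2s=3.0e-3, fa=0.0)


def _region(t1n: float, t2: float, md: float, fa: float, ecv: float,
            hct: float, b_pre: float, b_post: float, scar: bool = False) -> RegionValues:
    return RegionValues(
        t1_native_ms=t1n,
        t1_post_ms=t1_post_for_ecv(ecv, t1n, b_pre, b_post, hct),
        t2_ms=t2,
        md_mm2s=md,
        fa=fa,
        scar=scar,
    )


def default_timepoints(cohort: str = "infarct",
                       hematocrit: float = 0.33,
                       blood_t1_pre_ms: float = 1600.0,
                       blood_t1_post_ms: float = 280.0) -> list[TimepointSpec]:
    """The four study timepoints with the default ground-truth timeline."""
    if cohort not in ("control", "infarct"):
        raise ValueError("cohort must be 'control' or 'infarct'")
    blood = RegionValues(
        t1_native_ms=blood_t1_pre_ms, t1_post_ms=blood_t1_post_ms, **_BLOOD
    )
    tps: list[TimepointSpec] = []
    for label in TIMEPOINT_LABELS:
        remote_t2 = _REMOTE_T2[label] if cohort == "infarct" else 58.0
        remote = _region(
            _HEALTHY["t1_native_ms"], remote_t2, _HEALTHY["md_mm2s"], _HEALTHY["fa"],
            _HEALTHY_ECV, hematocrit, blood_t1_pre_ms, blood_t1_post_ms,
        )
        infarct: Optional[RegionValues] = None
        if cohort == "infarct":
            if label == "baseline":
                infarct = remote.model_copy()  # pre-infarct territory is healthy
            else:
                t1n, t2, fmd, ffa, fecv, scar = _INFARCT_TIMELINE[label]
                infarct = _region(
                    t1n, t2, _HEALTHY["md_mm2s"] * fmd, _HEALTHY["fa"] * ffa,
                    _HEALTHY_ECV * fecv, hematocrit, blood_t1_pre_ms,
                    blood_t1_post_ms, scar=scar,
                )
        ha_endo, ha_epi, tor, grs, gcs, gls = _MOTION[cohort][label]
        tps.append(TimepointSpec(
            label=label, remote=remote, infarct=infarct, blood=blood,
            ha_endo_deg=ha_endo, ha_epi_deg=ha_epi,
            torsion_slope_deg_per_mm=tor,
            grs_pct=grs, gcs_pct=gcs, gls_pct=gls,
        ))
    return tps


def default_phantom_config(cohort: str = "infarct", **overrides) -> PhantomConfig:
    """Study-default phantom for one cohort; keyword overrides are applied on top."""
    hct = overrides.pop("hematocrit", 0.33)
    b_pre = overrides.pop("blood_t1_pre_ms", 1600.0)
    b_post = overrides.pop("blood_t1_post_ms", 280.0)
    tps = overrides.pop("timepoints", default_timepoints(cohort, hct, b_pre, b_post))
    cfg = dict(
        timepoints=tps, hematocrit=hct,
        blood_t1_pre_ms=b_pre, blood_t1_post_ms=b_post,
    )
    if cohort == "control":
        cfg["infarct_sector_deg"] = None
    cfg.update(overrides)
    # keep the infarct territory proportional when only n_slices is overridden
    if "n_slices" in overrides and "infarct_slices" not in overrides:
        n = overrides["n_slices"]
        cfg["infarct_slices"] = (round(0.4 * n), round(0.9 * n))
    return PhantomConfig(**cfg)


class StudyConfig(BaseModel):
    """Whole simulated study: both cohorts over the four timepoints."""

    n_control: int = Field(default=4, ge=0)
    n_infarct: int = Field(default=5, ge=0)
    base_seed: int = 0
    subject_variation: float = Field(
        default=0.03, ge=0,
        description="SD of per-subject multiplicative jitter on ground-truth parameters",
    )
    noise_sigma_frac: float = Field(default=1.0 / 30.0, ge=0)
    grid_size: int = 96
    n_slices: int = 10
    timepoint_labels: Sequence[str] = TIMEPOINT_LABELS

    @model_validator(mode="after")
    def _check_labels(self) -> "StudyConfig":
        bad = set(self.timepoint_labels) - set(TIMEPOINT_LABELS)
        if bad:
            raise ValueError(f"unknown timepoint labels: {sorted(bad)}")
        if self.n_control + self.n_infarct == 0:
            raise ValueError("study needs at least one subject")
        return self
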