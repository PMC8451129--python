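"""Regional summaries and the study's comparison statistics.

The study contrasts regions (infarct vs remote within animals, remote vs
healthy controls between animals) with two-tailed Student's t-tests (paired or
pooled-variance unpaired), reports relative changes normalised by the
reference region, evaluates a control-vs-remote bias over all between-group
pairs, and correlates parameters with Pearson's r plus an OLS line with a
pointwise 95% confidence band.  No multiple-testing correction is applied
(matching the study design); outputs flag this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "REGION_TABLE_COLUMNS",
    "ContrastResult",
    "BiasResult",
    "CorrelationResult",
    "summarize_regions",
    "relative_change",
    "control_remote_bias",
    "compare_groups",
    "correlate",
]

REGION_TABLE_COLUMNS = [
    "subject", "group", "timepoint", "region", "parameter",
    "value", "units", "n_voxels", "sd",
]


def summarize_regions(
    maps: dict[str, np.ndarray],
    rois: dict[str, np.ndarray],
    subject: str,
    group: str,
    timepoint: str,
    units: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Arithmetic ROI means per parameter -> long-format region table rows.

    ``maps`` are per-voxel parameter maps (NaN = invalid voxel, excluded);
    ``rois`` are boolean masks.  Empty (or all-invalid) ROIs are omitted with
    a warning row-free result rather than raising.
    """
    units = units or {}
    rows = []
    for pname, arr in maps.items():
        for rname, roi in rois.items():
            vals = np.asarray(arr)[roi.astype(bool)]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                import warnings

                warnings.warn(f"empty ROI {rname!r} for parameter {pname!r}; row omitted")
                continue
            rows.append({
                "subject": subject, "group": group, "timepoint": timepoint,
                "region": rname, "parameter": pname,
                "value": float(vals.mean()), "units": units.get(pname, ""),
                "n_voxels": int(vals.size),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            })
    return pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)


@dataclass
class ContrastResult:
    per_subject_pct: pd.Series  # relative change per subject, percent
    mean_pct: float
    sd_pct: float
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    test_type: str = "paired"
    notes: dict = field(default_factory=dict)


def _pivot(table: pd.DataFrame, parameter: str, timepoint: str,
           region: str) -> pd.Series:
    sel = table[(table.parameter == parameter)
                & (table.timepoint == timepoint)
                & (table.region == region)]
    return sel.set_index("subject")["value"]


def relative_change(
    table: pd.DataFrame,
    parameter: str,
    timepoint: str,
    mode: str = "infarct_vs_remote",
    baseline_label: str = "baseline",
) -> ContrastResult:
    """Per-subject relative change (x_infarct - x_ref) / x_ref, in percent.

    ``infarct_vs_remote``: reference is the same subject's remote region at the
    same timepoint.  ``infarct_vs_baseline``: reference is the same subject's
    infarct territory at baseline.  Subjects with a zero reference are excluded
    with a note.  A paired t-test against zero change accompanies the summary.
    """
    x = _pivot(table, parameter, timepoint, "infarct")
    if mode == "infarct_vs_remote":
        ref = _pivot(table, parameter, timepoint, "remote")
    elif mode == "infarct_vs_baseline":
        ref = _pivot(table, parameter, baseline_label, "infarct")
    else:
        raise ValueError("mode must be 'infarct_vs_remote' or 'infarct_vs_baseline'")
    common = x.index.intersection(ref.index)
    x, ref = x.loc[common], ref.loc[common]
    excluded = list(common[ref == 0])
    keep = ref != 0
    rel = 100.0 * (x[keep] - ref[keep]) / ref[keep]
    t = p = None
    if len(rel) >= 2 and rel.std(ddof=1) > 0:
        res = sps.ttest_1samp(rel, 0.0)
        t, p = float(res.statistic), float(res.pvalue)
    return ContrastResult(
        per_subject_pct=rel,
        mean_pct=float(rel.mean()) if len(rel) else float("nan"),
        sd_pct=float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
        t_statistic=t, p_value=p, test_type="paired",
        notes={"mode": mode, "excluded_zero_reference": excluded,
               "multiple_testing_correction": "none"},
    )


@dataclass
class BiasResult:
    pair_values_pct: np.ndarray  # one per (control, infarct) pair
    mean_pct: float
    sd_pct: float
    n_pairs: int
    notes: dict = field(default_factory=dict)


def control_remote_bias(
    table: pd.DataFrame,
    parameter: str,
    timepoint: str,
) -> BiasResult:
    """All-pairs normalised difference remote (infarct animals) vs controls.

    d_ij = (remote_j - control_i) / ((remote_j + control_i) / 2) over every
    (control i, infarct j) pair, in percent; pairs with zero denominator are
    excluded.
    """
    ctrl = table[(table.parameter == parameter) & (table.timepoint == timepoint)
                 & (table.group == "control")]
    ctrl_vals = ctrl[ctrl.region.isin(["remote", "global"])].set_index("subject")["value"]
    rem = _pivot(table[table.group == "infarct"], parameter, timepoint, "remote")
    if len(ctrl_vals) == 0 or len(rem) == 0:
        raise ValueError("need at least one subject per group")
    c = ctrl_vals.to_numpy()[:, None]
    r = rem.to_numpy()[None, :]
    denom = (r + c) / 2.0
    ok = denom != 0
    d = 100.0 * (r - c)[ok] / denom[ok]
    return BiasResult(
        pair_values_pct=d,
        mean_pct=float(d.mean()), sd_pct=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        n_pairs=int(d.size),
        notes={"excluded_pairs": int((~ok).sum()),
               "multiple_testing_correction": "none"},
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-tailed Student's t-test; pooled variance when unpaired.

    Degenerate paired cases: all differences zero -> (0, 1); constant nonzero
    differences -> (signed inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal-length, corresponded samples")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return 0.0, 1.0
            return float(np.sign(d.mean()) * np.inf), 0.0
        res = sps.ttest_rel(a, b)
    else:
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            if np.allclose(a.mean(), b.mean()):
                return 0.0, 1.0
            return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    ci_x: np.ndarray  # grid over the x range
    ci_lower: np.ndarray  # pointwise 95% CI of the regression mean
    ci_upper: np.ndarray


def correlate(x: Sequence[float], y: Sequence[float],
              n_ci_points: int = 50) -> CorrelationResult:
    """Pearson correlation with OLS line and pointwise 95% confidence band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    xg = np.linspace(x.min(), x.max(), n_ci_points)
    pred = fit.get_prediction(sm.add_constant(xg)).summary_frame(alpha=0.05)
    return CorrelationResult(
        r=float(r), p_value=float(p),
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        n=int(x.size), ci_x=xg,
        ci_lower=pred["mean_ci_lower"].to_numpy(),
        ci_upper=pred["mean_ci_upper"].to_numpy(),
    )
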