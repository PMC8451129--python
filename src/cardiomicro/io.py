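"""File IO: NIfTI volumes, FSL-dialect bval/bvec, contour CSV, region tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ImageSeries
from .diffusion import DiffusionProtocol
from .mechanics import TrackedContours

__all__ = [
    "save_volume", "load_volume",
    "save_series", "load_series",
    "write_bval_bvec", "read_bval_bvec",
    "write_contours_csv", "read_contours_csv",
]


def _affine(pixel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def save_volume(path: str | Path, vol: np.ndarray,
                pixel_spacing_mm: float, slice_spacing_mm: float) -> None:
    """Save a (nz, ny, nx) volume as NIfTI in (x, y, z) axis order."""
    arr = np.asarray(vol, dtype=np.float32).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(arr, _affine(pixel_spacing_mm, slice_spacing_mm)), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return np.asarray(img.get_fdata()).transpose(2, 1, 0), float(zooms[0]), float(zooms[2])


def save_series(outdir: str | Path, name: str, series: ImageSeries) -> None:
    """Write a series as 4D NIfTI (x, y, z, frame) plus JSON frame metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arr = series.data.astype(np.float32).transpose(3, 2, 1, 0)
    nib.save(nib.Nifti1Image(arr, _affine(series.pixel_spacing_mm,
                                          series.slice_spacing_mm)),
             str(outdir / f"{name}.nii"))
    meta = {
        "modality": series.modality,
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "slice_spacing_mm": series.slice_spacing_mm,
        "frames": series.frame_meta.to_dict(orient="list"),
        "extra": {k: v for k, v in series.extra.items()
                  if isinstance(v, (int, float, str, bool))},
    }
    (outdir / f"{name}.json").write_text(json.dumps(meta, indent=1))


def load_series(outdir: str | Path, name: str) -> ImageSeries:
    outdir = Path(outdir)
    img = nib.load(str(outdir / f"{name}.nii"))
    meta = json.loads((outdir / f"{name}.json").read_text())
    data = np.asarray(img.get_fdata()).transpose(3, 2, 1, 0)
    return ImageSeries(
        data=data, frame_meta=pd.DataFrame(meta["frames"]),
        pixel_spacing_mm=meta["pixel_spacing_mm"],
        slice_spacing_mm=meta["slice_spacing_mm"],
        modality=meta.get("modality", "unknown"), extra=meta.get("extra", {}),
    )


def write_bval_bvec(prefix: str | Path, protocol: DiffusionProtocol) -> None:
    """FSL dialect: one whitespace row of b-values; three rows of x/y/z components."""
    prefix = Path(prefix)
    prefix.with_suffix(".bval").write_text(
        " ".join(f"{b:g}" for b in protocol.bvals) + "\n")
    lines = [" ".join(f"{v:.6f}" for v in protocol.bvecs[:, i]) for i in range(3)]
    prefix.with_suffix(".bvec").write_text("\n".join(lines) + "\n")


def read_bval_bvec(prefix: str | Path, averages: int = 1) -> DiffusionProtocol:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).reshape(3, -1).T
    return DiffusionProtocol(bvals=bvals, bvecs=bvecs, averages=averages)


def write_contours_csv(path: str | Path, tc: TrackedContours,
                       which: str = "mid") -> None:
    """Long-format CSV: slice, phase, point_id, x_mm, y_mm, z_mm."""
    pts = getattr(tc, which)
    if pts is None:
        raise ValueError(f"contour set {which!r} not present")
    nph, nsl, npt, _ = pts.shape
    t, s, p = np.meshgrid(np.arange(nph), np.arange(nsl), np.arange(npt),
                          indexing="ij")
    df = pd.DataFrame({
        "slice": s.ravel(), "phase": t.ravel(), "point_id": p.ravel(),
        "x_mm": pts[..., 0].ravel(), "y_mm": pts[..., 1].ravel(),
        "z_mm": pts[..., 2].ravel(),
    })
    df.to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> TrackedContours:
    df = pd.read_csv(path)
    nph = int(df["phase"].max()) + 1
    nsl = int(df["slice"].max()) + 1
    npt = int(df["point_id"].max()) + 1
    pts = np.zeros((nph, nsl, npt, 3))
    df = df.sort_values(["phase", "slice", "point_id"])
    for i, col in enumerate(("x_mm", "y_mm", "z_mm")):
        pts[..., i] = df[col].to_numpy().reshape(nph, nsl, npt)
    z0 = pts[0, :, 0, 2].copy()
    return TrackedContours(mid=pts, z0_mm=z0)
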