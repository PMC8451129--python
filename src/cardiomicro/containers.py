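"""Shared in-memory containers for simulated and acquired image series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ImageSeries:
    """A stack of short-axis image frames with per-frame acquisition metadata.

    ``data`` has shape ``(n_frames, n_slices, ny, nx)``.  ``frame_meta`` holds one
    row per frame; the columns depend on the modality (``ti_ms`` for inversion
    recovery, ``te_ms`` for multi-echo, ``bval``/``gx``/``gy``/``gz`` for DWI,
    ``phase`` for cine-like series).
    """

    data: np.ndarray
    frame_meta: pd.DataFrame
    pixel_spacing_mm: float
    slice_spacing_mm: float
    modality: str = "unknown"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries.data must be (n_frames, n_slices, ny, nx)")
        if len(self.frame_meta) != self.data.shape[0]:
            raise ValueError("frame_meta rows must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_ml(self) -> float:
        return self.pixel_spacing_mm**2 * self.slice_spacing_mm / 1000.0
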