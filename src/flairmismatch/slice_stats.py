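"""Per-slice reference statistics of parenchymal FLAIR intensity.

The segmentation criteria compare each lesion voxel against the mean and
standard deviation of normal-appearing parenchyma in the same 2D slice,
with the DWI lesion itself excluded so the reference is not contaminated by
the pathology being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, ImageVolume

DEFAULT_SLICE_AXIS = 2  # axial slices in canonical orientation
DEFAULT_MIN_SLICE_VOXELS = 50


@dataclass
class SliceStatistics:
    """Reference statistics of one slice: population mean/sd and voxel count.

    ``fallback`` is set when the slice had too few reference voxels and the
    whole-volume statistics were substituted.
    """

    slice_index: int
    mean: float
    sd: float
    n: int
    fallback: bool = False


@dataclass
class SliceStatsTable:
    """All per-slice records along one slice axis, plus broadcast helpers."""

    axis: int
    records: list[SliceStatistics]

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records):
            if rec.slice_index != i:
                raise ValueError("records must cover slices 0..n-1 in order")

    @property
    def n_slices(self) -> int:
        return len(self.records)

    def mean_array(self) -> np.ndarray:
        return np.array([r.mean for r in self.records])

    def sd_array(self) -> np.ndarray:
        return np.array([r.sd for r in self.records])

    def broadcast(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel (mean, sd) arrays for a volume of ``shape``."""
        if shape[self.axis] != self.n_slices:
            raise ValueError(
                f"stats cover {self.n_slices} slices but volume has "
                f"{shape[self.axis]} along axis {self.axis}"
            )
        bshape = [1, 1, 1]
        bshape[self.axis] = self.n_slices
        mu = self.mean_array().reshape(bshape)
        sd = self.sd_array().reshape(bshape)
        return np.broadcast_to(mu, shape), np.broadcast_to(sd, shape)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": [r.slice_index for r in self.records],
                "n": [r.n for r in self.records],
                "mean": [r.mean for r in self.records],
                "sd": [r.sd for r in self.records],
                "fallback": [r.fallback for r in self.records],
            }
        )


def compute_slice_stats(
    flair: ImageVolume,
    parenchyma: BinaryMask,
    roi: BinaryMask,
    slice_axis: int = DEFAULT_SLICE_AXIS,
    min_voxels: int = DEFAULT_MIN_SLICE_VOXELS,
) -> SliceStatsTable:
    """Mean/sd of FLAIR intensity per slice over parenchyma minus the ROI.

    The standard deviation is the population definition (divide by n).
    Slices with fewer than ``min_voxels`` reference voxels fall back to the
    whole-volume parenchyma-minus-ROI statistics so thin or heavily lesioned
    slices do not produce unstable thresholds.
    """
    if flair.shape != parenchyma.shape or flair.shape != roi.shape:
        raise ValueError("masks must be aligned to the FLAIR grid")
    if slice_axis not in (0, 1, 2):
        raise ValueError("slice_axis must be 0, 1 or 2")

    include = parenchyma.data & ~roi.data
    n_total = int(include.sum())
    if n_total == 0:
        raise ValueError("no reference tissue: parenchyma minus ROI is empty")

    vals_all = flair.data[include]
    global_mean = float(vals_all.mean())
    global_sd = float(vals_all.std())  # population sd

    data = np.moveaxis(flair.data, slice_axis, 0)
    inc = np.moveaxis(include, slice_axis, 0)
    records: list[SliceStatistics] = []
    for s in range(data.shape[0]):
        m = inc[s]
        n = int(m.sum())
        if n < min_voxels:
            records.append(
                SliceStatistics(s, global_mean, global_sd, n, fallback=True)
            )
        else:
            vals = data[s][m]
            records.append(
                SliceStatistics(s, float(vals.mean()), float(vals.std()), n)
            )
    return SliceStatsTable(axis=slice_axis, records=records)
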