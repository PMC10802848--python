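"""FLAIR parenchymal-hyperintensity segmentation inside the DWI lesion.

A voxel of the region of interest is marked hyperintense when at least one
of two criteria holds:

1. its intensity ratio to the contralateral (mirrored) location is strictly
   above ``ratio_threshold`` *and* the voxel is at least as bright as the
   slice mean plus ``sd_mult_low`` slice standard deviations, or
2. the voxel is strictly brighter than the slice mean plus ``sd_mult_high``
   slice standard deviations.

The brightness condition in criterion 1 prevents segmenting iso-intense
voxels whose contralateral twin happens to be hypo-intense; criterion 2
rescues voxels whose contralateral information is unusable (midline-crossing
lesions, contralateral white-matter hyperintensities).  The
``contralateral_only`` flag switches to a ratio-only ablation variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .measures import dice
from .mirroring import ContralateralField
from .slice_stats import SliceStatsTable
from .volumes import BinaryMask, ImageVolume

#: defaults chosen on the method's training data; the contralateral ratio
#: lies in the 1.07-1.15 range established for visual DWI/FLAIR mismatch.
DEFAULT_RATIO_THRESHOLD = 1.15
DEFAULT_SD_MULT_LOW = 0.25
DEFAULT_SD_MULT_HIGH = 1.25
#: relative floor for the contralateral denominator (fraction of volume max)
EPSILON_REL = 1e-6


@dataclass(frozen=True)
class SegmentationParams:
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    sd_mult_low: float = DEFAULT_SD_MULT_LOW
    sd_mult_high: float = DEFAULT_SD_MULT_HIGH
    contralateral_only: bool = False
    epsilon: float | None = None  # None -> EPSILON_REL * max intensity

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if not (self.sd_mult_high >= self.sd_mult_low >= 0):
            raise ValueError("need sd_mult_high >= sd_mult_low >= 0")

    def resolve_epsilon(self, flair: ImageVolume) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        return EPSILON_REL * float(np.max(np.abs(flair.data), initial=0.0))


def segment_hyperintensity(
    flair: ImageVolume,
    roi: BinaryMask,
    contra: ContralateralField,
    stats: SliceStatsTable,
    params: SegmentationParams | None = None,
) -> BinaryMask:
    """Apply the two hyperintensity criteria within the ROI (vectorized).

    The output mask is always a subset of the ROI.  Voxels with an invalid
    or near-zero contralateral sample cannot satisfy criterion 1 but remain
    eligible via criterion 2.
    """
    if params is None:
        params = SegmentationParams()
    if flair.shape != roi.shape:
        raise ValueError("ROI must be on the FLAIR grid")
    if contra.values.shape != flair.shape:
        raise ValueError("contralateral field must be on the FLAIR grid")
    mu, sd = stats.broadcast(flair.shape)

    intensity = flair.data
    eps = params.resolve_epsilon(flair)
    c_usable = contra.valid & (contra.values > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c_usable, intensity / contra.values, 0.0)
    ratio_ok = c_usable & (ratio > params.ratio_threshold)

    if params.contralateral_only:
        segmented = ratio_ok
    else:
        crit1 = ratio_ok & (intensity >= mu + params.sd_mult_low * sd)
        crit2 = intensity > mu + params.sd_mult_high * sd
        segmented = crit1 | crit2
    return BinaryMask.like(segmented & roi.data, roi)


@dataclass
class SweepEntry:
    params: SegmentationParams
    mask: BinaryMask
    dice: float


def sweep_parameters(
    flair: ImageVolume,
    roi: BinaryMask,
    contra: ContralateralField,
    stats: SliceStatsTable,
    reference: BinaryMask,
    base: SegmentationParams | None = None,
    ratio_delta: float = 0.08,
    mult_rel_delta: float = 0.20,
) -> list[SweepEntry]:
    """Hyper-parameter robustness sweep around the base parameters.

    Evaluates the 27 combinations of ratio_threshold +/- ``ratio_delta``
    (absolute) and each sd multiplier +/- ``mult_rel_delta`` (relative),
    reporting the DICE of each segmentation against ``reference``.  With
    the defaults this spans ratios 1.07-1.23 and multipliers at 80%-120%
    of their base values.
    """
    if base is None:
        base = SegmentationParams()
    ratios = [base.ratio_threshold + d for d in (-ratio_delta, 0.0, ratio_delta)]
    lows = [base.sd_mult_low * f for f in (1 - mult_rel_delta, 1.0, 1 + mult_rel_delta)]
    highs = [
        base.sd_mult_high * f for f in (1 - mult_rel_delta, 1.0, 1 + mult_rel_delta)
    ]
    if min(ratios) <= 0:
        raise ValueError("sweep produces a non-positive ratio threshold")

    entries: list[SweepEntry] = []
    for r, lo, hi in product(ratios, lows, highs):
        p = replace(base, ratio_threshold=r, sd_mult_low=lo, sd_mult_high=hi)
        mask = segment_hyperintensity(flair, roi, contra, stats, p)
        entries.append(SweepEntry(p, mask, dice(mask, reference)))
    return entries


def sweep_to_frame(entries: list[SweepEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ratio_threshold": [e.params.ratio_threshold for e in entries],
            "sd_mult_low": [e.params.sd_mult_low for e in entries],
            "sd_mult_high": [e.params.sd_mult_high for e in entries],
            "n_voxels": [e.mask.count for e in entries],
            "dice": [e.dice for e in entries],
        }
    )
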