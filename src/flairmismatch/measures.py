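"""Mismatch quantification, agreement metrics and the end-to-end pipeline.

The continuous DWI/FLAIR mismatch ratio is the segmented fraction of the
DWI lesion: 0 means no FLAIR hyperintensity inside the lesion (complete
mismatch, a recent stroke) and 1 means the whole lesion is already FLAIR
hyperintense (complete match).  The intensity measure — mean FLAIR
intensity inside the lesion over mean intensity of the remaining
parenchyma — flags cases where contralateral hyperintensity makes the
segmentation unreliable despite a low mismatch ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

from .mirroring import (
    RegistrationConfig,
    RegistrationResult,
    RigidTransform,
    contralateral_field,
    mirror_volume,
    register_mirrored,
    roi_self_overlap_fraction,
)
from .slice_stats import (
    DEFAULT_MIN_SLICE_VOXELS,
    DEFAULT_SLICE_AXIS,
    SliceStatsTable,
    compute_slice_stats,
)
from .volumes import BinaryMask, ImageVolume, resample_mask_to

log = logging.getLogger(__name__)

DEFAULT_OVERLAP_THRESHOLD = 0.20


class ExclusionReason(str, Enum):
    NONE = "none"
    EMPTY_DWI_ROI = "empty_dwi_roi"
    MIRROR_OVERLAP = "mirror_overlap"


def mismatch_ratio(flair_seg: BinaryMask, roi: BinaryMask) -> float:
    """|segmentation| / |ROI| on the shared grid; in [0, 1]."""
    n_roi = roi.count
    if n_roi == 0:
        raise ValueError("ROI is empty")
    if np.any(flair_seg.data & ~roi.data):
        raise ValueError("FLAIR segmentation is not a subset of the ROI")
    return flair_seg.count / n_roi


def intensity_measure(
    flair: ImageVolume, roi: BinaryMask, parenchyma: BinaryMask
) -> float:
    """Mean FLAIR intensity in the ROI over mean intensity of the rest of
    the parenchyma (ventricles/CSF excluded via the parenchyma mask)."""
    if roi.count == 0:
        raise ValueError("ROI is empty")
    rest = parenchyma.data & ~roi.data
    if not rest.any():
        raise ValueError("parenchyma minus ROI is empty")
    denom = float(flair.data[rest].mean())
    if denom == 0.0:
        raise ZeroDivisionError("mean parenchymal intensity outside the ROI is zero")
    return float(flair.data[roi.data].mean()) / denom


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    if a.shape != b.shape:
        raise ValueError("masks must share the grid")
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def image_weighted_dice(pairs: list[tuple[BinaryMask, BinaryMask]]) -> tuple[float, float]:
    """Unweighted mean and population sd of per-case DICE (each image counts
    equally regardless of lesion size)."""
    if not pairs:
        raise ValueError("need at least one pair of masks")
    scores = np.array([dice(a, b) for a, b in pairs])
    return float(scores.mean()), float(scores.std())


def point_biserial(continuous, binary) -> tuple[float, float]:
    """Point-biserial correlation between a continuous variable and 0/1
    labels, with a two-sided p-value from the t distribution (n-2 df).

    Numerically identical to the Pearson correlation with the labels coded
    as 0/1.
    """
    x = np.asarray(continuous, dtype=float)
    y = np.asarray(binary, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D and of equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if np.ptp(x) == 0:
        raise ValueError("continuous variable has zero variance")
    res = sps.pointbiserialr(y, x)
    return float(res.correlation), float(res.pvalue)


@dataclass
class MismatchResult:
    """Serializable per-case record of the full pipeline."""

    mismatch_ratio: float | None
    intensity_measure: float | None
    dwi_volume_voxels: int
    flair_volume_voxels: int
    dwi_volume_mm3: float
    flair_volume_mm3: float
    overlap_fraction: float | None
    excluded: bool
    exclusion_reason: str
    params: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)


@dataclass
class PipelineOutput:
    """Full pipeline output: the result record plus intermediate artifacts."""

    result: MismatchResult
    segmentation: BinaryMask | None = None
    transform: RigidTransform | None = None
    registration: RegistrationResult | None = None
    slice_stats: SliceStatsTable | None = None


def run_case(
    flair: ImageVolume,
    dwi_mask: BinaryMask,
    parenchyma: BinaryMask,
    params=None,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    slice_axis: int = DEFAULT_SLICE_AXIS,
    min_slice_voxels: int = DEFAULT_MIN_SLICE_VOXELS,
    registration_config: RegistrationConfig | None = None,
) -> PipelineOutput:
    """Run the full mismatch pipeline on one case.

    Stages: project the DWI lesion mask onto the FLAIR grid, mirror the
    FLAIR and register the mirrored volume back, check the ROI
    mirror-self-overlap exclusion rule, compute per-slice reference
    statistics, segment the hyperintensity and derive the mismatch ratio
    and intensity measure.  Exclusions (empty projected ROI; overlap
    fraction strictly above ``overlap_threshold``) are flagged results,
    not errors; for a mirror-overlap exclusion the measures are still
    reported but must be treated as unreliable.
    """
    from .segmentation import SegmentationParams, segment_hyperintensity

    if params is None:
        params = SegmentationParams()
    if parenchyma.shape != flair.shape:
        raise ValueError("parenchyma mask must be on the FLAIR grid")

    roi = resample_mask_to(dwi_mask, flair)
    vox_mm3 = flair.voxel_volume_mm3
    param_record = {
        "ratio_threshold": params.ratio_threshold,
        "sd_mult_low": params.sd_mult_low,
        "sd_mult_high": params.sd_mult_high,
        "contralateral_only": params.contralateral_only,
        "overlap_threshold": overlap_threshold,
        "slice_axis": slice_axis,
        "min_slice_voxels": min_slice_voxels,
    }

    if roi.count == 0:
        log.info("projected DWI ROI is empty; case excluded")
        return PipelineOutput(
            MismatchResult(
                mismatch_ratio=None,
                intensity_measure=None,
                dwi_volume_voxels=0,
                flair_volume_voxels=0,
                dwi_volume_mm3=0.0,
                flair_volume_mm3=0.0,
                overlap_fraction=None,
                excluded=True,
                exclusion_reason=ExclusionReason.EMPTY_DWI_ROI.value,
                params=param_record,
            )
        )

    mirrored = mirror_volume(flair)
    reg = register_mirrored(mirrored, flair, parenchyma, registration_config)
    log.info(
        "mirror registration: cost %.4g (identity %.4g), %d evaluations",
        reg.cost, reg.cost_identity, reg.n_evaluations,
    )

    overlap = roi_self_overlap_fraction(roi, reg.transform)
    excluded = overlap > overlap_threshold
    reason = ExclusionReason.MIRROR_OVERLAP if excluded else ExclusionReason.NONE
    log.info("ROI mirror self-overlap fraction: %.3f%s",
             overlap, " (excluded)" if excluded else "")

    contra = contralateral_field(flair, reg.transform)
    table = compute_slice_stats(flair, parenchyma, roi, slice_axis, min_slice_voxels)
    n_fallback = sum(r.fallback for r in table.records)
    if n_fallback:
        log.info("%d slices used whole-volume fallback statistics", n_fallback)

    seg = segment_hyperintensity(flair, roi, contra, table, params)
    ratio = mismatch_ratio(seg, roi)
    intensity = intensity_measure(flair, roi, parenchyma)

    result = MismatchResult(
        mismatch_ratio=ratio,
        intensity_measure=intensity,
        dwi_volume_voxels=roi.count,
        flair_volume_voxels=seg.count,
        dwi_volume_mm3=roi.count * vox_mm3,
        flair_volume_mm3=seg.count * vox_mm3,
        overlap_fraction=overlap,
        excluded=excluded,
        exclusion_reason=reason.value,
        params=param_record,
    )
    return PipelineOutput(
        result=result,
        segmentation=seg,
        transform=reg.transform,
        registration=reg,
        slice_stats=table,
    )
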