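"""Synthetic FLAIR/DWI phantoms with analytic ground truth.

The phantom is an ellipsoidal "brain" that is left-right symmetric about
the grid mid-sagittal plane, with two hypo-intense ventricles, an
ellipsoidal ischemic lesion whose FLAIR-hyperintense sub-region is known
exactly, and optional complications: a contralateral hyperintense
confounder (emulating age-related white-matter hyperintensity opposite the
stroke), a midline-crossing lesion, a whole-head rigid misalignment (so the
anatomical midplane is off the grid midplane) and additive Gaussian noise.
Geometry is deliberately schematic — the analytic truth masks are the
point — but every code path of the pipeline is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .mirroring import RigidTransform, _index_space_matrix
from .volumes import BinaryMask, ImageVolume


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically inconsistent."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Intensities are arbitrary units on a FLAIR-like scale; lengths are in
    voxels unless suffixed ``_mm``.  ``lesion_contralateral_ratio`` sets the
    FLAIR brightness of the hyperintense lesion part relative to its
    mirrored twin in the healthy hemisphere; ``lesion_fraction_hyper``
    controls how much of the DWI lesion is already FLAIR-visible (0 =
    complete mismatch, 1 = complete match).
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_intensity: float = 20.0
    parenchyma_intensity: float = 100.0
    ventricle_intensity: float = 40.0
    brain_axes: tuple[float, float, float] | None = None  # default 0.40/0.46/0.38 of shape
    lesion_center: tuple[float, float, float] | None = None  # default right hemisphere
    lesion_axes: tuple[float, float, float] = (5.0, 6.0, 4.0)
    lesion_contralateral_ratio: float = 1.5
    lesion_fraction_hyper: float = 1.0
    contralateral_confounder: tuple[tuple[float, float, float], tuple[float, float, float], float] | None = None  # (center, axes, intensity)
    midline_cross_fraction: float = 0.0
    misalignment_shift_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)
    misalignment_rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lesion_fraction_hyper <= 1.0):
            raise PhantomSpecError("lesion_fraction_hyper must be in [0, 1]")
        if not (0.0 <= self.midline_cross_fraction <= 1.0):
            raise PhantomSpecError("midline_cross_fraction must be in [0, 1]")
        if self.lesion_contralateral_ratio < 1.0:
            raise PhantomSpecError("lesion_contralateral_ratio must be >= 1")
        for name in ("background_intensity", "parenchyma_intensity", "ventricle_intensity"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be positive")

    def resolved_brain_axes(self) -> np.ndarray:
        if self.brain_axes is not None:
            return np.asarray(self.brain_axes, dtype=float)
        # in-plane eccentric (A-P longer than L-R), as real heads are
        return np.array(self.shape, dtype=float) * np.array([0.40, 0.46, 0.38])

    def resolved_lesion_center(self) -> np.ndarray:
        if self.lesion_center is not None:
            return np.asarray(self.lesion_center, dtype=float)
        n = np.array(self.shape, dtype=float)
        if self.midline_cross_fraction > 0.0:
            # near the midplane the ventricles are in the way; default to a
            # superior (high-z) location clear of them
            return np.array([0.50 * n[0], 0.45 * n[1], 0.68 * n[2]])
        return np.array([0.72 * n[0], 0.45 * n[1], 0.50 * n[2]])


@dataclass
class PhantomCase:
    flair: ImageVolume
    dwi: ImageVolume
    dwi_roi: BinaryMask
    parenchyma: BinaryMask
    truth_flair_hyper: BinaryMask
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if np.any(self.truth_flair_hyper.data & ~self.dwi_roi.data):
            raise PhantomSpecError("truth mask must be inside the DWI ROI")
        if np.any(self.dwi_roi.data & ~self.parenchyma.data):
            raise PhantomSpecError("DWI ROI must be inside the parenchyma")


def _ellipsoid(coords, center, axes) -> np.ndarray:
    """Ellipsoid membership evaluated at continuous coordinates (3, ...)."""
    center = np.asarray(center, dtype=float)
    axes = np.asarray(axes, dtype=float)
    d = sum(((coords[k] - center[k]) / axes[k]) ** 2 for k in range(3))
    return d <= 1.0


#: full width (voxels) of the smoothstep intensity ramp at tissue
#: interfaces, emulating partial-volume edges; interiors stay exactly constant
RAMP_VOX = 2.4


def _radial(coords, center, axes) -> np.ndarray:
    """Normalized ellipsoidal radius (1.0 on the surface)."""
    center = np.asarray(center, dtype=float)
    axes = np.asarray(axes, dtype=float)
    return np.sqrt(sum(((coords[k] - center[k]) / axes[k]) ** 2 for k in range(3)))


def _ramp_halfwidth(axes) -> float:
    # clamp so thin structures (ventricles) keep a real interior plateau
    return min(0.25, RAMP_VOX / (2.0 * float(np.min(axes))))


def _soft(r: np.ndarray, h: float) -> np.ndarray:
    """1 inside (r <= 1-h), 0 outside (r >= 1+h), quintic smoothstep across.

    The C2-continuous profile keeps plateaus exactly constant while avoiding
    the interpolation ringing a kinked (linear) ramp would cause.
    """
    u = np.clip((1.0 + h - r) / (2.0 * h), 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


def _centered_affine(spec: PhantomSpec) -> np.ndarray:
    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    affine = np.diag([vox[0], vox[1], vox[2], 1.0])
    affine[:3, 3] = -vox * (np.array(spec.shape) - 1) / 2.0
    return affine


def _cap_fraction(d: float, a: float) -> float:
    """Volume fraction of an ellipsoid lying beyond a plane at signed
    distance d from its center along the semi-axis a (d=-a: 1, d=a: 0)."""
    return (a - d) ** 2 * (2 * a + d) / (4 * a**3)


def _midline_offset(fraction: float, a: float) -> float:
    """Signed center offset from the midplane giving the requested crossing
    fraction for an ellipsoid with x semi-axis a."""
    if fraction <= 0.0:
        return a  # fully on one side (not used; caller keeps its center)
    return float(optimize.brentq(lambda d: _cap_fraction(d, a) - fraction, -a, a))


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomCase:
    """Build one phantom case deterministically from its spec and seed.

    All geometry is evaluated analytically in an *anatomical* frame: each
    grid voxel index is pulled back through the inverse head misalignment
    before the ellipsoid membership tests, so a misaligned phantom has
    crisp edges at the perturbed pose rather than interpolation-smoothed
    ones.
    """
    if spec is None:
        spec = PhantomSpec()
    shape = tuple(spec.shape)
    affine = _centered_affine(spec)
    n0 = shape[0]
    grid_center = (np.array(shape, dtype=float) - 1.0) / 2.0
    midplane_x = grid_center[0]

    shift = np.asarray(spec.misalignment_shift_vox, dtype=float)
    rot = np.deg2rad(spec.misalignment_rot_deg)
    coords = np.indices(shape, dtype=float)
    if np.any(shift != 0.0) or np.any(rot != 0.0):
        world_center = affine[:3, :3] @ grid_center + affine[:3, 3]
        t_mm = shift * np.asarray(spec.voxel_size_mm)
        t = RigidTransform(t_mm, rot, world_center)
        m = _index_space_matrix(t, affine)  # anatomical idx = m @ grid idx
        flat = coords.reshape(3, -1)
        coords = (m[:3, :3] @ flat + m[:3, 3:4]).reshape(coords.shape)

    brain_axes = spec.resolved_brain_axes()
    vent_axes = np.array([2.5, 0.16 * shape[1], 0.11 * shape[2]])
    vent_dx = 0.09 * n0
    vent_centers = (grid_center - [vent_dx, 0, 0], grid_center + [vent_dx, 0, 0])
    # mirror-symmetric internal structures.  Their contrast breaks the
    # rotational and up-down/front-back near-symmetries of the bare
    # ellipsoid, the way real cortical and deep-gray anatomy does; without
    # them the mirror registration problem is ill-conditioned
    n = np.array(shape, dtype=float)
    nucleus_axes = np.array([3.5, 3.0, 4.0])
    structures = [
        # deep-nuclei pair, inferior and posterior of center
        (np.array([grid_center[0] - 0.14 * n[0], 0.66 * n[1], 0.40 * n[2]]),
         nucleus_axes, 0.80 * spec.parenchyma_intensity),
        (np.array([grid_center[0] + 0.14 * n[0], 0.66 * n[1], 0.40 * n[2]]),
         nucleus_axes, 0.80 * spec.parenchyma_intensity),
        # bright anterior band, superior of center
        (np.array([grid_center[0], 0.78 * n[1], 0.54 * n[2]]),
         np.array([0.25 * n[0], 0.10 * n[1], 0.23 * n[2]]),
         1.15 * spec.parenchyma_intensity),
        # dark posterior-inferior region
        (np.array([grid_center[0], 0.30 * n[1], 0.30 * n[2]]),
         np.array([0.16 * n[0], 0.125 * n[1], 0.10 * n[2]]),
         0.85 * spec.parenchyma_intensity),
    ]
    h_brain = _ramp_halfwidth(brain_axes)
    h_vent = _ramp_halfwidth(vent_axes)

    def base_intensity_at(c):
        """Symmetric pre-lesion intensity at anatomical coordinates (3, ...).

        Interfaces carry a linear partial-volume-like ramp; plateaus are
        exactly constant.
        """
        w_brain = _soft(_radial(c, grid_center, brain_axes), h_brain)
        out = spec.background_intensity + (
            spec.parenchyma_intensity - spec.background_intensity
        ) * w_brain
        for s_center, s_axes, s_intensity in structures:
            w = _soft(_radial(c, s_center, s_axes), _ramp_halfwidth(s_axes))
            out += (s_intensity - spec.parenchyma_intensity) * w * w_brain
        for vc in vent_centers:
            w = _soft(_radial(c, vc, vent_axes), h_vent)
            out += (spec.ventricle_intensity - spec.parenchyma_intensity) * w * w_brain
        return out

    # masks stay binary and keep clear of the intensity ramps: the
    # parenchyma core stops before the brain-edge ramp and excludes the
    # ventricles together with their ramp
    brain_core = _radial(coords, grid_center, brain_axes) <= 1.0 - h_brain - 0.01
    vent_excl = np.zeros(shape, dtype=bool)
    for vc in vent_centers:
        vent_excl |= _radial(coords, vc, vent_axes) < 1.0 + h_vent + 0.03
    parenchyma = brain_core & ~vent_excl
    brain = _radial(coords, grid_center, brain_axes) <= 1.0
    structure_region = np.zeros(shape, dtype=bool)
    for s_center, s_axes, _ in structures:
        structure_region |= (
            _radial(coords, s_center, s_axes) < 1.0 + _ramp_halfwidth(s_axes) + 0.02
        )

    lesion_center = spec.resolved_lesion_center()
    if spec.midline_cross_fraction > 0.0:
        d = _midline_offset(spec.midline_cross_fraction, float(spec.lesion_axes[0]))
        lesion_center = lesion_center.copy()
        lesion_center[0] = midplane_x + d
    lesion = _ellipsoid(coords, lesion_center, spec.lesion_axes)
    if np.any(lesion & ~parenchyma):
        raise PhantomSpecError(
            "lesion extends outside the parenchyma (brain minus ventricles)"
        )
    if np.any(lesion & structure_region):
        raise PhantomSpecError(
            "lesion intersects an internal structure; move the lesion"
        )

    flair = base_intensity_at(coords)

    if spec.contralateral_confounder is not None:
        c_center, c_axes, c_intensity = spec.contralateral_confounder
        confounder = _ellipsoid(coords, c_center, c_axes)
        if np.any(confounder & lesion):
            raise PhantomSpecError("confounder must not intersect the lesion")
        flair[confounder & parenchyma] = float(c_intensity)

    # hyperintense sub-region: a deterministic anterior-to-posterior split of
    # the lesion voxels, so lesion_fraction_hyper is hit to rounding accuracy
    vox = np.argwhere(lesion)
    avox = coords[:, vox[:, 0], vox[:, 1], vox[:, 2]]  # anatomical coords
    order = np.lexsort((avox[0], avox[2], avox[1]))
    n_hyper = int(round(spec.lesion_fraction_hyper * len(vox)))
    hyper_vox = vox[order[:n_hyper]]
    truth = np.zeros(shape, dtype=bool)
    truth[hyper_vox[:, 0], hyper_vox[:, 1], hyper_vox[:, 2]] = True
    # contralateral twin: mirror across the anatomical midplane; the twin
    # intensity is read off the symmetric pre-lesion, pre-confounder base
    twin_coords = avox[:, order[:n_hyper]].copy()
    twin_coords[0] = (n0 - 1) - twin_coords[0]
    twin_vals = base_intensity_at(twin_coords)
    flair[hyper_vox[:, 0], hyper_vox[:, 1], hyper_vox[:, 2]] = (
        twin_vals * spec.lesion_contralateral_ratio
    )

    dwi = base_intensity_at(coords)
    dwi[lesion] = 1.8 * spec.parenchyma_intensity  # bright acute lesion

    roi = lesion

    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        flair = flair + rng.normal(0.0, spec.noise_sd, shape)
        dwi = dwi + rng.normal(0.0, spec.noise_sd, shape)

    flair_vol = ImageVolume(flair, affine)
    return PhantomCase(
        flair=flair_vol,
        dwi=ImageVolume(dwi, affine.copy()),
        dwi_roi=BinaryMask(roi, affine.copy()),
        parenchyma=BinaryMask(parenchyma, affine.copy()),
        truth_flair_hyper=BinaryMask(truth, affine.copy()),
        spec=spec,
    )


@dataclass
class CohortSpec:
    """Distribution of a synthetic cohort for correlation testing.

    ``match_fraction`` of the cases are "match" cases (lesion essentially
    FLAIR-visible, fraction-hyper drawn from ``hyper_range_match``); the
    rest are "mismatch" cases drawn from ``hyper_range_mismatch``.  Lesion
    side, position and size are jittered per case.
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    match_fraction: float = 0.5
    hyper_range_mismatch: tuple[float, float] = (0.0, 0.08)
    hyper_range_match: tuple[float, float] = (0.92, 1.0)
    center_jitter_vox: float = 2.0
    axis_jitter_vox: float = 1.0


def generate_cohort(
    n: int, seed: int = 0, cohort: CohortSpec | None = None
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Sample ``n`` phantom cases plus a truth table for correlation tests.

    The table codes ``flair_visible`` = 1 for match cases (lesion already
    hyperintense on FLAIR, i.e. no DWI/FLAIR mismatch) and ``mismatch`` =
    1 - ``flair_visible``; the pipeline's mismatch ratio should correlate
    positively with ``flair_visible``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cohort is None:
        cohort = CohortSpec()
    rng = np.random.default_rng(seed)
    n_match = int(round(cohort.match_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_match] = 1
    rng.shuffle(labels)

    base = cohort.base
    shape = np.array(base.shape, dtype=float)
    cases: list[PhantomCase] = []
    rows = []
    for i in range(n):
        lo, hi = (
            cohort.hyper_range_match if labels[i] else cohort.hyper_range_mismatch
        )
        frac = float(rng.uniform(lo, hi))
        # rejection-sample lesion geometry: a jittered lesion occasionally
        # clips a ventricle, structure or the brain edge
        for _ in range(50):
            side = rng.choice([-1.0, 1.0])
            cx = (0.5 + side * 0.22) * shape[0]
            jitter = rng.uniform(-cohort.center_jitter_vox, cohort.center_jitter_vox, 3)
            center = np.array([cx, 0.45 * shape[1], 0.50 * shape[2]]) + jitter
            axes = np.asarray(base.lesion_axes, dtype=float) + rng.uniform(
                -cohort.axis_jitter_vox, cohort.axis_jitter_vox, 3
            )
            spec = replace(
                base,
                lesion_center=tuple(center),
                lesion_axes=tuple(axes),
                lesion_fraction_hyper=frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                case = generate_phantom(spec)
                break
            except PhantomSpecError:
                continue
        else:
            raise PhantomSpecError("could not place a lesion after 50 attempts")
        cases.append(case)
        rows.append(
            {
                "case_id": f"case_{i:03d}",
                "flair_visible": int(labels[i]),
                "mismatch": int(1 - labels[i]),
                "lesion_fraction_hyper": frac,
                "lesion_side": "left" if side < 0 else "right",
                "seed": spec.seed,
            }
        )
    return cases, pd.DataFrame(rows)


def write_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write one case as uncompressed-friendly NIfTI files."""
    from .volumes import save_mask, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(case.flair, out / "flair.nii.gz")
    save_volume(case.dwi, out / "dwi.nii.gz")
    save_mask(case.dwi_roi, out / "dwi_roi.nii.gz")
    save_mask(case.parenchyma, out / "parenchyma.nii.gz")
    save_mask(case.truth_flair_hyper, out / "truth_flair_hyper.nii.gz")


def write_cohort(
    cases: list[PhantomCase], table: pd.DataFrame, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for row, case in zip(table.itertuples(), cases):
        write_case(case, out / row.case_id)
    table.to_csv(out / "cases.csv", index=False)
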