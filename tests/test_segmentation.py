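"""The two hyperintensity criteria, their ablation and the parameter sweep."""

import numpy as np
import pytest

import flairmismatch as fm
from flairmismatch.mirroring import ContralateralField
from flairmismatch.slice_stats import SliceStatistics, SliceStatsTable


def loop_oracle(flair, roi, cvals, cvalid, mu, sd, params, eps):
    """Literal per-voxel transcription of the two criteria (slice axis 2)."""
    out = np.zeros(flair.shape, dtype=bool)
    for i, j, k in np.ndindex(flair.shape):
        if not roi[i, j, k]:
            continue
        intensity = flair[i, j, k]
        c_ok = cvalid[i, j, k] and cvals[i, j, k] > eps
        ratio_ok = c_ok and intensity / cvals[i, j, k] > params.ratio_threshold
        if params.contralateral_only:
            out[i, j, k] = ratio_ok
            continue
        crit1 = ratio_ok and intensity >= mu[k] + params.sd_mult_low * sd[k]
        crit2 = intensity > mu[k] + params.sd_mult_high * sd[k]
        out[i, j, k] = crit1 or crit2
    return out


def stats_table(mu, sd):
    return SliceStatsTable(
        axis=2,
        records=[
            SliceStatistics(i, float(m), float(s), 100)
            for i, (m, s) in enumerate(zip(mu, sd))
        ],
    )


def one_voxel_case(intensity, contra, mu, sd, valid=True):
    """A 1x1x1 case for spelling out the criteria on a single voxel."""
    flair = fm.ImageVolume(np.full((1, 1, 1), float(intensity)), np.eye(4))
    roi = fm.BinaryMask(np.ones((1, 1, 1), dtype=bool), np.eye(4))
    field = ContralateralField(
        np.full((1, 1, 1), float(contra)), np.full((1, 1, 1), valid)
    )
    return flair, roi, field, stats_table([mu], [sd])


@pytest.mark.parametrize(
    "intensity,contra,mu,sd,expected,why",
    [
        (120.0, 100.0, 90.0, 100.0, True, "ratio 1.2 and brightness mu+0.3sd: criterion 1"),
        (100.0, 100.0, 100.0, 10.0, False, "iso-intense symmetric voxel fails both"),
        (110.0, 100.0, 45.0, 50.0, True, "ratio 1.10 too low but mu+1.3sd: criterion 2"),
        (130.0, 100.0, 180.0, 100.0, False, "ratio 1.3 but mu-0.5sd: hypo-intense twin guard"),
    ],
)
def test_criteria_on_single_voxels(intensity, contra, mu, sd, expected, why):
    flair, roi, field, stats = one_voxel_case(intensity, contra, mu, sd)
    seg = fm.segment_hyperintensity(flair, roi, field, stats)
    assert bool(seg.data[0, 0, 0]) == expected, why


def test_ratio_threshold_is_strict():
    # intensity/contra exactly 1.15 must NOT satisfy criterion 1
    flair, roi, field, stats = one_voxel_case(115.0, 100.0, 0.0, 100.0)
    assert not fm.segment_hyperintensity(flair, roi, field, stats).data.any()


def test_invalid_contralateral_still_eligible_via_criterion2():
    flair, roi, field, stats = one_voxel_case(200.0, 100.0, 50.0, 10.0, valid=False)
    seg = fm.segment_hyperintensity(flair, roi, field, stats)
    assert seg.data[0, 0, 0]  # 200 > 50 + 1.25*10


def test_near_zero_contralateral_disables_criterion1():
    flair, roi, field, stats = one_voxel_case(100.0, 1e-12, 100.0, 10.0)
    assert not fm.segment_hyperintensity(flair, roi, field, stats).data.any()


def test_contralateral_only_variant_ignores_slice_stats():
    flair, roi, field, stats = one_voxel_case(130.0, 100.0, 500.0, 10.0)
    params = fm.SegmentationParams(contralateral_only=True)
    seg = fm.segment_hyperintensity(flair, roi, field, stats, params)
    assert seg.data[0, 0, 0]  # ratio 1.3 alone segments; brightness ignored


def random_case(rng, shape):
    flair = fm.ImageVolume(rng.uniform(0, 200, shape), np.eye(4))
    roi = fm.BinaryMask(rng.random(shape) > 0.5, np.eye(4))
    cvals = rng.uniform(0, 200, shape)
    cvalid = rng.random(shape) > 0.2
    mu = rng.uniform(50, 150, shape[2])
    sd = rng.uniform(0, 40, shape[2])
    return flair, roi, cvals, cvalid, mu, sd


def test_vectorized_equals_scalar_loop():
    rng = np.random.default_rng(7)
    for trial in range(5):
        shape = (10, 9, 6)
        flair, roi, cvals, cvalid, mu, sd = random_case(rng, shape)
        params = fm.SegmentationParams(contralateral_only=bool(trial % 2))
        field = ContralateralField(cvals, cvalid)
        seg = fm.segment_hyperintensity(flair, roi, field, stats_table(mu, sd), params)
        eps = params.resolve_epsilon(flair)
        expected = loop_oracle(flair.data, roi.data, cvals, cvalid, mu, sd, params, eps)
        np.testing.assert_array_equal(seg.data, expected)


def test_output_is_subset_of_roi():
    rng = np.random.default_rng(11)
    flair, roi, cvals, cvalid, mu, sd = random_case(rng, (12, 12, 8))
    seg = fm.segment_hyperintensity(
        flair, roi, ContralateralField(cvals, cvalid), stats_table(mu, sd)
    )
    assert not np.any(seg.data & ~roi.data)


def test_monotone_in_thresholds():
    """Raising any threshold can only remove voxels."""
    rng = np.random.default_rng(13)
    flair, roi, cvals, cvalid, mu, sd = random_case(rng, (14, 12, 8))
    field = ContralateralField(cvals, cvalid)
    stats = stats_table(mu, sd)
    base = fm.segment_hyperintensity(flair, roi, field, stats,
                                     fm.SegmentationParams(1.10, 0.2, 1.0))
    for params in [
        fm.SegmentationParams(1.30, 0.2, 1.0),
        fm.SegmentationParams(1.10, 0.6, 1.0),
        fm.SegmentationParams(1.10, 0.2, 1.8),
    ]:
        tighter = fm.segment_hyperintensity(flair, roi, field, stats, params)
        assert not np.any(tighter.data & ~base.data)


def test_scale_equivariance_given_same_field():
    rng = np.random.default_rng(17)
    flair, roi, cvals, cvalid, mu, sd = random_case(rng, (12, 10, 6))
    field = ContralateralField(cvals, cvalid)
    seg = fm.segment_hyperintensity(flair, roi, field, stats_table(mu, sd))
    c = 2.0  # exact in floating point; ratios and z-scores both scale out
    scaled = fm.segment_hyperintensity(
        fm.ImageVolume(flair.data * c, np.eye(4)),
        roi,
        ContralateralField(cvals * c, cvalid),
        stats_table(mu * c, sd * c),
    )
    np.testing.assert_array_equal(seg.data, scaled.data)


def test_params_validation():
    with pytest.raises(ValueError):
        fm.SegmentationParams(ratio_threshold=0.0)
    with pytest.raises(ValueError):
        fm.SegmentationParams(sd_mult_low=1.0, sd_mult_high=0.5)


class TestSweep:
    def _inputs(self):
        rng = np.random.default_rng(19)
        flair, roi, cvals, cvalid, mu, sd = random_case(rng, (12, 10, 6))
        ref = fm.BinaryMask(rng.random((12, 10, 6)) > 0.5, np.eye(4))
        return flair, roi, ContralateralField(cvals, cvalid), stats_table(mu, sd), ref

    def test_zero_deltas_give_27_identical_rows(self):
        flair, roi, field, stats, ref = self._inputs()
        entries = fm.sweep_parameters(flair, roi, field, stats, ref,
                                      ratio_delta=0.0, mult_rel_delta=0.0)
        assert len(entries) == 27
        assert len({e.dice for e in entries}) == 1

    def test_default_grid_spans_documented_ratio_range(self):
        flair, roi, field, stats, ref = self._inputs()
        entries = fm.sweep_parameters(flair, roi, field, stats, ref)
        ratios = sorted({e.params.ratio_threshold for e in entries})
        assert ratios[0] == pytest.approx(1.07)
        assert ratios[-1] == pytest.approx(1.23)
        lows = sorted({e.params.sd_mult_low for e in entries})
        assert lows == [pytest.approx(0.2), pytest.approx(0.25), pytest.approx(0.3)]

    def test_degenerate_grid_rejected(self):
        flair, roi, field, stats, ref = self._inputs()
        with pytest.raises(ValueError):
            fm.sweep_parameters(flair, roi, field, stats, ref, ratio_delta=2.0)

    def test_frame_roundtrip(self):
        flair, roi, field, stats, ref = self._inputs()
        entries = fm.sweep_parameters(flair, roi, field, stats, ref)
        frame = fm.sweep_to_frame(entries)
        assert len(frame) == 27
        assert frame.dice.between(0, 1).all()
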