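"""Threshold statistic, MIPs, SNR, and percent-change arithmetic."""

import numpy as np
import pytest

from cerevasc.acbv import (
    AcbvParams,
    acbv_threshold,
    compute_acbv,
    measure_snr,
    mip,
    percent_change,
    percent_increase,
    roi_mask,
)
from cerevasc.grids import LabelVolume, Volume


def make_pair(values, labels=None, spacing=0.1, name_map=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.ones(values.shape, dtype=np.int16)
    vol = Volume(values=values, spacing=spacing)
    lab = LabelVolume(
        labels=np.asarray(labels),
        spacing=spacing,
        name_map=name_map or {"roi": (1,)},
    )
    return vol, lab


class TestRoiMask:
    def test_single_label_count_matches_histogram(self, young_subject):
        lab = young_subject.labels
        mask = roi_mask(lab, "hippocampus")
        assert mask.sum() == np.count_nonzero(lab.labels == lab.name_map["hippocampus"][0])

    def test_union_roi_is_sum_of_disjoint_members(self, young_subject):
        lab = young_subject.labels
        union = roi_mask(lab, "ventricular_system").sum()
        members = sum(
            roi_mask(lab, name).sum()
            for name in (
                "lateral_ventricles",
                "third_ventricle",
                "cerebral_aqueduct",
                "fourth_ventricle",
            )
        )
        assert union == members

    def test_unknown_roi_lists_available(self, young_subject):
        with pytest.raises(KeyError, match="available"):
            roi_mask(young_subject.labels, "amygdala")

    def test_empty_roi_flagged(self):
        _, lab = make_pair(np.zeros((4, 4, 4)), name_map={"roi": (1,), "ghost": (9,)})
        with pytest.warns(UserWarning, match="empty"):
            mask = roi_mask(lab, "ghost")
        assert not mask.any()


class TestThreshold:
    def test_constant_roi_threshold_is_the_constant(self):
        vol, lab = make_pair(np.full((3, 3, 3), 7.0))
        assert acbv_threshold(vol, lab.labels == 1) == pytest.approx(7.0)

    def test_matches_brute_force_on_enumerated_values(self, rng):
        vals = rng.uniform(0, 100, size=(3, 3, 3))
        vol, lab = make_pair(vals)
        thr = acbv_threshold(vol, lab.labels == 1, AcbvParams(k=2.5))
        flat = vals.ravel()
        assert thr == pytest.approx(flat.mean() + 2.5 * flat.std(ddof=1), rel=1e-12)

    def test_k_zero_gives_mean(self, rng):
        vals = rng.normal(size=(4, 4, 4))
        vol, lab = make_pair(vals)
        assert acbv_threshold(vol, lab.labels == 1, AcbvParams(k=0.0)) == pytest.approx(
            vals.mean()
        )


class TestComputeAcbv:
    def test_thousand_and_one_voxel_example(self):
        # 1000 voxels at 0 plus one at 1000: mean = 0.999, sample SD (n-1)
        # = 31.607, threshold = 0.999 + 2.5 * 31.607 = 80.02, and
        # aCBV = 100/1001 ~ 0.0999%
        vals = np.zeros(1001)
        vals[-1] = 1000.0
        vol, lab = make_pair(vals.reshape(7, 11, 13))
        res = compute_acbv(vol, lab, "roi")
        assert res.threshold == pytest.approx(0.999001 + 2.5 * 31.60699, abs=1e-3)
        assert res.acbv == pytest.approx(100.0 / 1001.0, rel=1e-9)

    def test_constant_roi_degenerate_hundred_percent(self):
        vol, lab = make_pair(np.full((3, 3, 3), 5.0))
        with pytest.warns(UserWarning, match="degenerate"):
            res = compute_acbv(vol, lab, "roi")
        assert res.acbv == 100.0
        assert res.degenerate

    def test_affine_intensity_invariance(self, rng):
        vals = rng.normal(10, 3, size=(6, 6, 6))
        vol, lab = make_pair(vals)
        base = compute_acbv(vol, lab, "roi")
        vol2, _ = make_pair(4.2 * vals + 17.0)
        rescaled = compute_acbv(vol2, lab, "roi")
        assert rescaled.n_supra == base.n_supra

    def test_monotone_nonincreasing_in_k(self, rng):
        vals = rng.normal(size=(8, 8, 8))
        vol, lab = make_pair(vals)
        counts = [
            compute_acbv(vol, lab, "roi", AcbvParams(k=k)).n_supra
            for k in (0.0, 1.0, 2.0, 2.5, 3.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_matches_two_pass_reference_exactly(self, rng):
        # exhaustive reference on a small ROI: compute moments, then count
        vals = rng.normal(50, 10, size=(10, 10, 10))
        vol, lab = make_pair(vals)
        res = compute_acbv(vol, lab, "roi")
        flat = vals.ravel()
        thr = flat.mean() + 2.5 * flat.std(ddof=1)
        assert res.n_supra == int((flat >= thr).sum())

    def test_misaligned_grids_rejected(self):
        vol, _ = make_pair(np.zeros((4, 4, 4)))
        _, lab = make_pair(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="shapes differ"):
            compute_acbv(vol, lab, "roi")

    def test_noiseless_phantom_recovery(self, young_subject):
        rec = young_subject
        res = compute_acbv(rec.volume, rec.labels, "whole_brain")
        assert res.acbv == pytest.approx(
            rec.truth_fraction_by_roi["whole_brain"], rel=0.15
        )


class TestMip:
    def test_known_column_maxima(self):
        vals = np.arange(8).reshape(2, 2, 2).astype(float)
        vol = Volume(values=vals, spacing=1.0)
        assert np.array_equal(mip(vol, "z"), vals.max(axis=2))
        assert np.array_equal(mip(vol, "x"), vals.max(axis=0))

    def test_projection_of_known_max_plane(self):
        vals = np.zeros((4, 4, 4))
        vals[:, :, 2] = np.arange(16).reshape(4, 4)
        vol = Volume(values=vals, spacing=1.0)
        assert np.array_equal(mip(vol, "z"), vals[:, :, 2])

    def test_masked_equals_unmasked_for_zero_background(self, rng):
        vals = np.zeros((6, 6, 6))
        brain = np.zeros((6, 6, 6), dtype=bool)
        brain[1:5, 1:5, 1:5] = True
        vals[brain] = rng.uniform(1, 2, size=brain.sum())
        vol = Volume(values=vals, spacing=1.0)
        masked = mip(vol, "y", mask=brain)
        unmasked = mip(vol, "y")
        rows = brain.any(axis=1)
        assert np.array_equal(masked[rows], unmasked[rows])

    def test_invalid_axis(self):
        vol = Volume(values=np.zeros((2, 2, 2)), spacing=1.0)
        with pytest.raises(ValueError):
            mip(vol, "w")


class TestSnr:
    def test_simple_ratio(self, rng):
        vals = np.zeros((10, 10, 10))
        signal = np.zeros_like(vals, dtype=bool)
        noise = np.zeros_like(signal)
        signal[:2], noise[8:] = True, True
        vals[signal] = 10.0
        vals[noise] = rng.normal(0, 1.0, size=noise.sum())
        vol = Volume(values=vals, spacing=1.0)
        snr, _ = measure_snr(vol, [signal], noise)
        assert snr == pytest.approx(10.0 / vals[noise].std(ddof=1))

    def test_scale_invariance(self, rng):
        vals = rng.uniform(1, 5, size=(8, 8, 8))
        signal = np.zeros((8, 8, 8), dtype=bool)
        noise = np.zeros_like(signal)
        signal[:3], noise[6:] = True, True
        vol1 = Volume(values=vals, spacing=1.0)
        vol2 = Volume(values=3.7 * vals, spacing=1.0)
        assert measure_snr(vol1, [signal], noise)[0] == pytest.approx(
            measure_snr(vol2, [signal], noise)[0]
        )

    def test_zero_noise_sd_rejected(self):
        vol = Volume(values=np.ones((4, 4, 4)), spacing=1.0)
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="zero SD"):
            measure_snr(vol, [m], m)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,later,loss",
        [(1.64, 1.24, 24.39), (458.18, 362.94, 20.79), (1.99, 1.43, 28.14)],
    )
    def test_reported_losses(self, ref, later, loss):
        assert round(percent_change(ref, later), 2) == loss

    def test_no_change_is_zero(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_gain_convention(self):
        assert round(percent_increase(439.78, 460.40), 2) == 4.69

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
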