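"""Jacobian maps, voxel-wise statistics, FDR, and volumetry."""

import numpy as np
import pytest
from scipy import stats as sps

from cerevasc.grids import DisplacementField, Volume
from cerevasc.morphometry import (
    fdr_mask,
    group_mean_ci,
    jacobian_map,
    roi_volume,
    volume_summaries,
    voxelwise_group_test,
)
from cerevasc.synthetic import generate_displacement, volumetry_labels

SHAPE = (20, 20, 20)
SPACING = 0.25


class TestJacobian:
    def test_zero_field_det_one_everywhere(self):
        field = DisplacementField(vectors=np.zeros(SHAPE + (3,)), spacing=SPACING)
        det = jacobian_map(field)
        assert np.allclose(det.values, 1.0)

    def test_affine_exact_in_interior(self):
        field, expected = generate_displacement("affine", SHAPE, SPACING, affine=1.1 * np.eye(3))
        det = jacobian_map(field).values
        interior = det[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 1.331, atol=1e-12)

    def test_general_affine_exact(self):
        A = np.array([[1.05, 0.02, 0.0], [0.01, 0.97, 0.03], [0.0, 0.02, 1.08]])
        field, expected = generate_displacement("affine", SHAPE, SPACING, affine=A)
        det = jacobian_map(field).values
        assert np.allclose(det[1:-1, 1:-1, 1:-1], np.linalg.det(A), atol=1e-10)

    def test_sinusoid_second_order_convergence(self):
        # halving the grid spacing should shrink the interior error ~4x
        errors = []
        for n in (16, 32, 64):
            shape = (n, 8, 8)
            spacing = 4.0 / n
            field, analytic = generate_displacement(
                "sinusoid", shape, spacing, amplitude=0.2, wavelength=4.0
            )
            det = jacobian_map(field).values
            err = np.abs(det - analytic.values)[1:-1, 1:-1, 1:-1].max()
            errors.append(err)
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.3)
        assert errors[1] / errors[2] == pytest.approx(4.0, rel=0.3)

    def test_composed_affines_multiply(self):
        A = 1.04 * np.eye(3)
        B = np.diag([0.98, 1.02, 1.01])
        _, detA = generate_displacement("affine", SHAPE, SPACING, affine=A)
        _, detB = generate_displacement("affine", SHAPE, SPACING, affine=B)
        field_ab, _ = generate_displacement("affine", SHAPE, SPACING, affine=A @ B)
        det = jacobian_map(field_ab).values[1:-1, 1:-1, 1:-1]
        assert np.allclose(det, detA.values[0, 0, 0] * detB.values[0, 0, 0], atol=1e-10)

    def test_mean_det_of_full_period_warp_is_one(self):
        # a sinusoid over a whole wavelength conserves volume on average
        n = 40
        field, _ = generate_displacement(
            "sinusoid", (n, 6, 6), 4.0 / n, amplitude=0.15, wavelength=4.0
        )
        det = jacobian_map(field).values
        assert det[:, 3, 3].mean() == pytest.approx(1.0, abs=1e-3)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_map(DisplacementField(vectors=np.zeros((2, 5, 5, 3)), spacing=1.0))


class TestFdr:
    @staticmethod
    def brute_force_bh(p, q):
        """Literal step-up definition, O(m^2)-naive."""
        p = np.asarray(p)
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                k_star = rank
        reject = np.zeros(m, dtype=bool)
        if k_star:
            reject[order[:k_star]] = True
        return reject

    def test_worked_example(self):
        p = np.array([0.001, 0.02, 0.03, 0.04, 0.2])
        mask = fdr_mask(p.reshape(1, 1, 5), q=0.05)
        assert mask.ravel().tolist() == [True, True, True, True, False]

    def test_all_ones_none_rejected(self):
        assert not fdr_mask(np.ones((3, 3, 3)), q=0.05).any()

    def test_all_zeros_all_rejected(self):
        assert fdr_mask(np.zeros((3, 3, 3)), q=0.05).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 200))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            got = fdr_mask(p.reshape(1, 1, -1), q=0.05).ravel()
            assert np.array_equal(got, self.brute_force_bh(p, 0.05))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=(4, 4, 4))
        small = fdr_mask(p, q=0.01)
        large = fdr_mask(p, q=0.10)
        assert np.all(large[small])

    def test_respects_analysis_mask(self, rng):
        p = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0] = True
        out = fdr_mask(p, q=0.05, analysis_mask=mask)
        assert out[0].all() and not out[1:].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fdr_mask(np.ones((2, 2, 2)), analysis_mask=np.zeros((2, 2, 2), dtype=bool))


def _jacobian_group(rng, n, shape, mu=0.0, sigma=0.02, bump=None):
    vols = []
    for _ in range(n):
        logj = rng.normal(mu, sigma, size=shape)
        if bump is not None:
            region, delta = bump
            logj[region] += delta
        vols.append(Volume(values=np.exp(logj), spacing=1.0))
    return vols


class TestVoxelwise:
    def test_identical_groups_nothing_significant(self):
        base = np.exp(np.random.default_rng(0).normal(0, 0.01, size=(8, 8, 8)))
        groups = {
            "a": [Volume(values=base, spacing=1.0)] * 3,
            "b": [Volume(values=base, spacing=1.0)] * 3,
        }
        res = voxelwise_group_test(groups)
        assert not res.significant.any()
        assert np.all(res.p[1:-1, 1:-1, 1:-1] == 1.0)

    def test_planted_expansion_detected(self, rng):
        shape = (12, 12, 12)
        region = np.zeros(shape, dtype=bool)
        region[4:8, 4:8, 4:8] = True
        young = _jacobian_group(rng, 10, shape)
        old = _jacobian_group(rng, 10, shape, bump=(region, 0.10))
        res = voxelwise_group_test({"young": young, "old": old})
        interior = np.zeros(shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        planted = region & interior
        # log-effect of 0.10 at sigma 0.02, n=10/10: enormous power
        assert res.significant[planted].mean() > 0.95
        assert res.significant[~region & interior].mean() < 0.05
        assert np.all(res.direction[planted] > 0)

    def test_single_voxel_matches_reference_t_test(self, rng):
        a = rng.normal(0, 0.05, size=(6, 3, 3, 3))
        b = rng.normal(0.03, 0.05, size=(6, 3, 3, 3))
        groups = {
            "a": [Volume(values=np.exp(x), spacing=1.0) for x in a],
            "b": [Volume(values=np.exp(x), spacing=1.0) for x in b],
        }
        res = voxelwise_group_test(groups, exclude_boundary=False)
        ref = sps.ttest_ind(a[:, 1, 1, 1], b[:, 1, 1, 1])
        assert res.p[1, 1, 1] == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.statistic[1, 1, 1] == pytest.approx(ref.statistic, rel=1e-9)

    def test_three_groups_use_anova(self, rng):
        groups = {
            g: _jacobian_group(rng, 4, (5, 5, 5)) for g in ("a", "b", "c")
        }
        res = voxelwise_group_test(groups, exclude_boundary=False)
        arrs = [np.log(np.stack([v.values for v in groups[g]])) for g in groups]
        ref = sps.f_oneway(*[a[:, 2, 2, 2] for a in arrs])
        assert res.p[2, 2, 2] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_few_subjects_rejected(self):
        v = Volume(values=np.ones((4, 4, 4)), spacing=1.0)
        with pytest.raises(ValueError):
            voxelwise_group_test({"a": [v], "b": [v, v]})


class TestVolumetry:
    def test_exact_count_times_spacing_cubed(self):
        labels = volumetry_labels(brain_mm3=439.78, ventricle_mm3=5.16, spacing=0.1)
        res = roi_volume(labels, "whole_brain")
        assert res.volume_mm3 == pytest.approx(439.78, abs=0.001)
        assert res.n_voxels == 439780

    def test_thousand_voxels_is_one_mm3(self):
        from cerevasc.grids import LabelVolume

        arr = np.zeros((10, 10, 10), dtype=np.int16)
        arr.ravel()[:1000] = 1
        lab = LabelVolume(labels=arr, spacing=0.1, name_map={"roi": (1,)})
        assert roi_volume(lab, "roi").volume_mm3 == pytest.approx(1.0)

    def test_union_volume_is_sum_of_members(self):
        labels = volumetry_labels(brain_mm3=100.0, ventricle_mm3=2.0, spacing=0.1)
        union = roi_volume(labels, "ventricular_system").volume_mm3
        members = sum(
            roi_volume(labels, n).volume_mm3
            for n in ("lateral_ventricles", "third_ventricle", "cerebral_aqueduct", "fourth_ventricle")
        )
        assert union == pytest.approx(members, rel=1e-12)

    def test_empty_roi_warns_zero(self):
        labels = volumetry_labels(brain_mm3=50.0, ventricle_mm3=0.0, spacing=0.1)
        with pytest.warns(UserWarning, match="empty"):
            assert roi_volume(labels, "third_ventricle").volume_mm3 == 0.0


class TestSummaries:
    VOLS = {
        "2-4": {"whole_brain": 439.78, "ventricular_system": 5.16},
        "24-26": {"whole_brain": 460.40, "ventricular_system": 6.54},
    }

    def test_reported_percentages(self):
        out = volume_summaries(self.VOLS)
        assert round(out["24-26"]["whole_brain_pct_change"], 2) == 4.69
        assert round(out["24-26"]["ventricular_system_pct_change"], 2) == 26.74
        assert round(out["2-4"]["ventricular_fraction_pct"], 2) == 1.17

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            volume_summaries({"a": {"whole_brain": 0.0}, "b": {"whole_brain": 1.0}})

    def test_group_mean_ci_contains_mean(self, rng):
        x = rng.normal(10, 2, size=30)
        m, lo, hi = group_mean_ci(x)
        assert lo < m < hi
        assert m == pytest.approx(x.mean())
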