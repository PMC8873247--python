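"""References, z-values, group statistics, ROC and identification."""

import numpy as np
import pytest

from ppgnorm import beatnorm as bn
from ppgnorm import compare as cmp
from ppgnorm import synthetic as syn


def _summary(means, subject="s01", session="d1", sds=None):
    means = np.asarray(means, dtype=float)
    sds = np.ones(10) if sds is None else np.asarray(sds, float)
    return bn.DatasetSummary(means, sds, 35, subject_id=subject, session_id=session)


class TestReferences:
    def test_identical_sessions_yield_unusable_reference(self):
        ref = cmp.build_individual_reference([_summary(np.arange(10), session=f"d{i}")
                                              for i in range(5)])
        assert not ref.usable
        with pytest.raises(cmp.CompareError):
            cmp.z_values(_summary(np.arange(10)), ref)

    def test_session_mean_arithmetic(self):
        vals = [9, 10, 11, 10, 10]
        sessions = [_summary(np.full(10, v), session=f"d{i}") for i, v in enumerate(vals)]
        ref = cmp.build_individual_reference(sessions)
        assert ref.n == 5
        np.testing.assert_allclose(ref.means, 10.0)
        np.testing.assert_allclose(ref.sds, np.sqrt(0.5))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(5, 10))
        sessions = [_summary(row, session=f"d{i}") for i, row in enumerate(mat)]
        ref = cmp.build_individual_reference(sessions)
        np.testing.assert_allclose(ref.means, mat.mean(axis=0))
        np.testing.assert_allclose(ref.sds, mat.std(axis=0, ddof=1))

    def test_mixed_subjects_rejected(self):
        with pytest.raises(cmp.CompareError, match="mixed"):
            cmp.build_individual_reference(
                [_summary(np.arange(10), "s01"), _summary(np.arange(10), "s02")]
            )

    def test_group_reference_across_subjects(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(8, 10))
        ref = cmp.build_group_reference(list(mat), "group1")
        assert ref.n == 8
        np.testing.assert_allclose(ref.means, mat.mean(axis=0))
        np.testing.assert_allclose(ref.sds, mat.std(axis=0, ddof=1))
        with pytest.raises(cmp.CompareError):
            cmp.build_group_reference([mat[0]])

    def test_json_roundtrip(self):
        ref = cmp.Reference("s07", 5, np.arange(10.0), np.ones(10))
        back = cmp.Reference.from_json(ref.to_json())
        assert back.label == "s07" and back.n == 5
        np.testing.assert_allclose(back.means, ref.means)


class TestZValues:
    def test_reference_against_itself_is_zero(self):
        ref = cmp.Reference("r", 5, np.arange(10.0), np.ones(10))
        z = cmp.z_values(_summary(np.arange(10.0)), ref)
        np.testing.assert_array_equal(z.z_values, np.zeros(10))
        assert z.mean_abs_z == 0.0

    def test_one_sd_offset_gives_mean_abs_z_of_one(self):
        ref = cmp.Reference("r", 5, np.zeros(10), np.full(10, 2.0))
        z = cmp.z_values(_summary(np.full(10, 2.0)), ref)
        assert z.mean_abs_z == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        m, rm, rs = rng.normal(size=10), rng.normal(size=10), rng.uniform(0.5, 2, 10)
        ref = cmp.Reference("r", 4, rm, rs)
        z = cmp.z_values(_summary(m), ref)
        np.testing.assert_allclose(z.z_values, (m - rm) / rs)
        assert z.mean_abs_z == pytest.approx(np.mean(np.abs((m - rm) / rs)))

    def test_own_session_bounded_by_max_standardized_deviation(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(5, 10))
        sessions = [_summary(row, session=f"d{i}") for i, row in enumerate(mat)]
        ref = cmp.build_individual_reference(sessions)
        bound = np.max(np.abs((mat - ref.means) / ref.sds))
        for s in sessions:
            assert cmp.z_values(s, ref).mean_abs_z <= bound + 1e-12


class TestClassify:
    def test_target_at_reference_means_wins(self):
        a = cmp.Reference("a", 5, np.zeros(10), np.ones(10))
        b = cmp.Reference("b", 5, np.full(10, 3.0), np.ones(10))
        out = cmp.classify(_summary(np.zeros(10)), a, b)
        assert out.label == "a" and out.score > 0 and not out.tie

    def test_equidistant_target_ties_toward_first(self):
        a = cmp.Reference("a", 5, np.zeros(10), np.ones(10))
        b = cmp.Reference("b", 5, np.full(10, 2.0), np.ones(10))
        out = cmp.classify(_summary(np.full(10, 1.0)), a, b)
        assert out.label == "a" and out.score == 0.0 and out.tie


class TestGroupArithmetic:
    def test_antisymmetry_under_group_swap(self):
        t12 = cmp.group_t(10.5, 2.0, 8, 9.1, 1.5, 7)
        t21 = cmp.group_t(9.1, 1.5, 7, 10.5, 2.0, 8)
        assert t12 == pytest.approx(-t21)

    def test_equal_means_give_zero_t(self):
        assert cmp.group_t(5.0, 1.0, 8, 5.0, 2.0, 7) == 0.0

    def test_zero_pooled_se_is_an_error(self):
        assert cmp.pooled_se(0.0, 8, 0.0, 7) == 0.0
        with pytest.raises(cmp.CompareError):
            cmp.group_t(1.0, 0.0, 8, 2.0, 0.0, 7)

    def test_t_critical_median_and_normal_limit(self):
        assert cmp.t_critical(0.5, 3) == pytest.approx(0.0, abs=1e-12)
        assert cmp.t_critical(0.05, 10**6) == pytest.approx(1.645, abs=1e-3)
        with pytest.raises(cmp.CompareError):
            cmp.t_critical(1.5, 7)

    def test_model_from_subject_means_and_summary(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 10))
        b = rng.normal(size=(7, 10)) + 0.5
        res = cmp.GroupDifferenceModel.from_subject_means(a, b).fit()
        np.testing.assert_allclose(res.mean_diff, a.mean(0) - b.mean(0))
        expected_se = np.sqrt(a.std(0, ddof=1) ** 2 / 8 + b.std(0, ddof=1) ** 2 / 7)
        np.testing.assert_allclose(res.pooled_se, expected_se)
        assert res.df == 7
        text = res.summary()
        assert "t_crit" in text and len(text.splitlines()) == 14
        assert list(res.frame.columns) == ["M1", "SD1", "M2", "SD2", "SD12", "t", "significant"]


class TestRoc:
    def test_perfect_separation(self):
        out = cmp.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        assert cmp.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(cmp.CompareError):
            cmp.roc_curve([0.1, 0.9], [1, 1])

    def test_auc_equals_pairwise_concordance_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            conc = np.mean((pos[:, None] > neg[None, :])
                           + 0.5 * (pos[:, None] == neg[None, :]))
            assert cmp.roc_curve(scores, labels).auc == pytest.approx(conc)


class TestIdentificationExperiment:
    def _cohort(self, session_sd=0.0, within=1e-6, seed=0):
        return syn.simulate_identification_cohort(
            seed=seed, within_sd=within, session_sd=session_sd, segment_corr=0.0
        )

    def test_zero_noise_identification_is_perfect(self):
        cohort = self._cohort()
        out = cmp.identification_experiment(
            cohort.reference, cohort.tests, cohort.groups, "individual"
        )
        assert out.auc == pytest.approx(1.0, abs=1e-6)

    def test_reference_test_overlap_rejected(self):
        cohort = self._cohort()
        tests = [s for ss in cohort.reference.values() for s in ss]
        with pytest.raises(cmp.CompareError, match="overlap"):
            cmp.identification_experiment(cohort.reference, tests, cohort.groups, "group")

    def test_group_result_is_serializable(self):
        cohort = self._cohort(session_sd=1.0, within=1.6, seed=1)
        out = cmp.identification_experiment(
            cohort.reference, cohort.tests, cohort.groups, "group"
        )
        import json

        d = json.loads(out.to_json())
        assert d["mode"] == "group"
        assert 0.0 <= d["auc"] <= 1.0
        with pytest.raises(cmp.CompareError):
            cmp.identification_experiment(
                cohort.reference, cohort.tests, cohort.groups, "nonsense"
            )
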