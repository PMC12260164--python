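"""Metric correctness against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import f1_score

from tests.conftest import make_patient, statics_only_cohort
from txlearn.evaluation import (
    auprc,
    cohens_d,
    cross_validate,
    effect_size_magnitude,
    paired_ite_comparison,
    recovery_report,
    subgroup_ite_summaries,
    wilcoxon_signed_rank,
)
from txlearn.models import FunctionRiskModel
from txlearn.records import LabeledPatient, WAVE1


# ---------------------------------------------------------------- AUPRC oracle
def auprc_oracle(y, s):
    """Exhaustive threshold enumeration + trapezoid, written independently
    of the vectorised implementation."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    points = []
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        points.append((tp / (tp + fn), tp / (tp + fp)))
    points.sort(key=lambda rp: rp[0])
    area = 0.0
    prev_r, prev_p = 0.0, points[0][1]
    for r, p in points:
        area += (r - prev_r) * (p + prev_p) / 2.0
        prev_r, prev_p = r, p
    return area


class TestAUPRC:
    def test_hand_case_matches_enumeration(self):
        y = np.array([1, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.4, 0.1])
        assert auprc(y, s) == pytest.approx(auprc_oracle(y, s), abs=1e-12)

    def test_perfect_classifier_scores_one(self):
        y = np.array([0, 0, 1, 1, 0])
        s = np.array([0.1, 0.2, 0.8, 0.9, 0.3])
        assert auprc(y, s) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        s = np.full(10, 0.5)
        assert auprc(y, s) == pytest.approx(0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.integers(0, 1), min_size=2, max_size=20),
        raw=st.lists(st.integers(0, 9), min_size=20, max_size=20),
    )
    def test_matches_enumeration_on_small_sets(self, y, raw):
        y = np.array(y)
        if y.sum() == 0:
            y[0] = 1
        s = np.array(raw[: len(y)]) / 10.0
        assert auprc(y, s) == pytest.approx(auprc_oracle(y, s), abs=1e-12)

    def test_undefined_without_positives(self):
        with pytest.raises(ValueError):
            auprc(np.zeros(4, dtype=int), np.arange(4) / 4)


# ----------------------------------------------------------- Wilcoxon oracles
def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for bits in range(total):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_all_positive_differences_rank_sum(self):
        # pairs (2,1),(3,1),(4,1),(5,1): |d| = 1,2,3,4 -> W+ = 1+2+3+4
        w, z, p, n = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0]))
        assert w == 10.0 and n == 4

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = rng.normal(0.2, 1.0, n)
        d = np.where(d == 0, 0.17, d)
        # perturb to avoid tied |d| (exact path requires no ties)
        d += rng.normal(0, 1e-6, n)
        _, _, p, _ = wilcoxon_signed_rank(d)
        assert p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-10)

    def test_normal_approximation_close_to_exact_at_n50(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.15, 1.0, 50)
        _, _, p_approx, _ = wilcoxon_signed_rank(d, exact_max_n=0)
        p_exact = float(stats.wilcoxon(d, zero_method="wilcox",
                                       method="exact").pvalue)
        assert abs(p_approx - p_exact) < 0.01

    def test_zero_differences_are_dropped(self):
        d = np.array([0.0, 0.0, 1.0, -2.0, 3.0])
        _, _, _, n = wilcoxon_signed_rank(d)
        assert n == 3

    def test_all_zero_differences(self):
        w, z, p, n = wilcoxon_signed_rank(np.zeros(5))
        assert (w, z, p, n) == (0.0, 0.0, 1.0, 0)


class TestEffectSizeBands:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.602, "Large"), (0.497, "Moderate"), (0.202, "Small"),
            (0.5, "Large"), (0.3, "Moderate"), (0.1, "Small"),
            (0.2999999, "Small"), (0.05, "Negligible"), (0.0, "Negligible"),
        ],
    )
    def test_banding_is_left_closed(self, r, label):
        assert effect_size_magnitude(r) == label

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1))
    def test_banding_is_a_step_function(self, r):
        label = effect_size_magnitude(r)
        expected = ("Large" if r >= 0.5 else "Moderate" if r >= 0.3
                    else "Small" if r >= 0.1 else "Negligible")
        assert label == expected

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            effect_size_magnitude(-0.1)


class TestPairedComparison:
    def test_identical_vectors_are_null(self):
        a = np.array([0.1, 0.2, 0.3, -0.1])
        res = paired_ite_comparison(a, a.copy())
        assert res.cohens_d == 0.0
        assert res.r == 0.0
        assert res.magnitude == "Negligible"

    def test_shifted_vectors_have_positive_d_and_large_r(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, 200)
        res = paired_ite_comparison(a + 0.2, a, "ACEI", "BB")
        assert res.cohens_d > 1.0
        assert res.d_ci[0] < res.cohens_d < res.d_ci[1]
        assert res.magnitude == "Large"
        assert res.median_a > res.median_b

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ite_comparison(np.zeros(3), np.zeros(4))


class TestSubgroups:
    def _patients(self, ages):
        return [make_patient(pid=i, age=a) for i, a in enumerate(ages)]

    def test_identical_groups_have_zero_dispersion(self):
        tau = np.array([0.1, 0.1, 0.1, 0.1])
        df = subgroup_ite_summaries(tau, self._patients([45, 45, 85, 85]))
        assert df.attrs["median_dispersion"] == 0.0

    def test_constructed_medians_give_dispersion(self):
        tau = np.array([0.1, 0.1, -0.1, -0.1])
        df = subgroup_ite_summaries(tau, self._patients([45, 45, 85, 85]))
        assert df.attrs["median_dispersion"] == pytest.approx(0.2)

    def test_single_group_equals_overall_summary(self):
        tau = np.array([0.0, 0.1, 0.2, 0.3])
        df = subgroup_ite_summaries(tau, self._patients([50, 51, 52, 53]))
        assert len(df) == 1
        assert df["median"].iloc[0] == pytest.approx(np.median(tau))

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError):
            subgroup_ite_summaries(np.zeros(1), self._patients([50]), "income")


class TestRecovery:
    def test_perfect_recovery(self):
        tau = np.array([0.0, 0.1, -0.2, 0.3])
        rec = recovery_report(tau, tau)
        assert rec.bias == 0.0 and rec.pehe == 0.0
        assert rec.rank_correlation == pytest.approx(1.0)

    def test_constant_offset(self):
        tau = np.array([0.0, 0.1, -0.2, 0.3])
        rec = recovery_report(tau + 0.05, tau)
        assert rec.bias == pytest.approx(0.05)
        assert rec.pehe == pytest.approx(0.05)

    def test_pehe_bounds_bias(self):
        rng = np.random.default_rng(2)
        tau = rng.normal(0, 0.1, 500)
        rec = recovery_report(tau + rng.normal(0, 0.05, 500), tau)
        assert rec.pehe >= abs(rec.bias)

    def test_permutation_null_has_no_rank_correlation(self):
        rng = np.random.default_rng(4)
        tau = rng.normal(0, 0.1, 10000)
        rec = recovery_report(rng.permutation(tau), tau)
        assert abs(rec.rank_correlation) < 0.05


class TestCrossValidation:
    def _cohort(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            simd = int(rng.integers(1, 11))
            y = int(simd > 5)  # outcome readable from an unscaled static
            out.append(
                LabeledPatient(make_patient(pid=i, simd=simd), 1, {}, y, 180)
            )
        return out

    def test_perfect_classifier_maxes_all_metrics(self):
        cohort = self._cohort()
        # SIMD passes through unscaled (static feature 3), so thresholding
        # its sigmoid at 0.5 reproduces the label exactly in every fold
        factory = lambda: FunctionRiskModel(
            lambda e: 1.0 / (1.0 + np.exp(-(e.static_features[0][3] - 5.5)))
        )
        metrics = cross_validate(cohort, WAVE1, factory, k=5, seed=0)
        assert metrics.auprc == [1.0] * 5
        assert metrics.accuracy == [1.0] * 5
        assert metrics.f1 == [1.0] * 5

    def test_constant_score_auprc_equals_fold_prevalence(self):
        cohort = self._cohort()
        factory = lambda: FunctionRiskModel(lambda e: 0.5)
        metrics = cross_validate(cohort, WAVE1, factory, k=4, seed=0)
        y = np.array([lp.y for lp in cohort])
        # stratified folds hold the prevalence (up to rounding)
        for ap in metrics.auprc:
            assert ap == pytest.approx(y.mean(), abs=0.03)

    def test_single_class_outcome_rejected(self):
        cohort = self._cohort()
        for lp in cohort:
            lp.y = 0
        with pytest.raises(ValueError):
            cross_validate(cohort, WAVE1, lambda: FunctionRiskModel(lambda e: 0.5))


def test_subgroup_density_plot_written_to_file(tmp_path):
    from txlearn.evaluation import plot_subgroup_densities

    rng = np.random.default_rng(0)
    patients = [make_patient(pid=i, age=float(rng.uniform(40, 90)))
                for i in range(60)]
    tau = rng.normal(0, 0.05, 60)
    out = tmp_path / "ite_by_age.svg"
    plot_subgroup_densities(tau, patients, "age_band", out)
    assert out.exists() and out.stat().st_size > 0


def test_f1_invariant_to_duplicating_the_evaluation_set():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50)
    s = rng.random(50)
    pred = (s >= 0.5).astype(int)
    once = f1_score(y, pred)
    twice = f1_score(np.tile(y, 2), np.tile(pred, 2))
    assert once == pytest.approx(twice)
    assert auprc(y, s) == pytest.approx(auprc(np.tile(y, 2), np.tile(s, 2)))
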