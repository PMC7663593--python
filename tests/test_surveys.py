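"""Survey statistics: Lilliefors gate, exact Wilcoxon, summaries, instants."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

import rgstress as rg
from rgstress.surveys import (
    SPSLRecord,
    default_instant_epochs,
    records_from_frame,
    spsl_frame,
)


def brute_force_wilcoxon(x, y):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Independent of the package's dynamic-programming path: walks the full
    2^n sign patterns, mid-ranking tied absolute differences.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    sums = np.asarray(sums)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_five_one_sided_shifts_give_exact_p(self):
        res = rg.wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "wilcoxon-exact"

    def test_identical_samples_give_p_one(self):
        res = rg.wilcoxon_signed_rank([3, 3, 3], [3, 3, 3])
        assert res.p_value == 1.0
        assert "zero" in res.notes

    def test_two_sided_p_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 6, 12).astype(float)
        y = rng.integers(1, 6, 12).astype(float)
        a = rg.wilcoxon_signed_rank(x, y)
        b = rg.wilcoxon_signed_rank(y, x)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_brute_force_enumeration_small_n(self):
        # ties and zeros included: integer-valued pairs, n <= 8
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            x = rng.integers(1, 6, n).astype(float)
            y = rng.integers(1, 6, n).astype(float)
            ours = rg.wilcoxon_signed_rank(x, y).p_value
            oracle = brute_force_wilcoxon(x, y)
            assert ours == pytest.approx(oracle, abs=1e-12), (x, y)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = 12
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            ours = rg.wilcoxon_signed_rank(x, y).p_value
            ref = ss.wilcoxon(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = x + 0.5 + rng.standard_normal(60)
        res = rg.wilcoxon_signed_rank(x, y)
        assert res.method == "wilcoxon-normal"
        ref = ss.wilcoxon(x, y, method="approx", correction=True).pvalue
        assert res.p_value == pytest.approx(ref, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rg.wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestLilliefors:
    def test_uniform_sample_detectably_non_normal(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 1000)
        res = rg.lilliefors_test(x, seed=0)
        assert res.p_value < 0.01

    def test_p_values_bit_reproducible_given_seed(self):
        x = np.random.default_rng(5).standard_normal(50)
        a = rg.lilliefors_test(x, seed=42)
        b = rg.lilliefors_test(x, seed=42)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf

        rng = np.random.default_rng(6)
        for n in (10, 40, 200):
            x = rng.standard_normal(n)
            ours = rg.lilliefors_test(x, seed=0).statistic
            ref_stat, _ = sm_lf(x, dist="norm")
            assert ours == pytest.approx(ref_stat, rel=1e-9)

    def test_normal_samples_rarely_rejected(self):
        # level check: p > 0.05 in >= 90% of repetitions on true normals
        rng = np.random.default_rng(7)
        keep = 0
        for i in range(100):
            x = rng.standard_normal(1000)
            res = rg.lilliefors_test(x, mc_samples=1000, seed=i)
            keep += res.p_value > 0.05
        assert keep >= 90

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            rg.lilliefors_test([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            rg.lilliefors_test([2.0, 2.0, 2.0, 2.0])


class TestSummarizeSPSL:
    def cohort_frame(self, seed=0, n=10, means=(2, 4, 2, 2), sd=0.5):
        cohort = rg.default_cohort(n_subjects=2 * n, seed=seed)
        return rg.generate_spsl(cohort, means, sd, seed=seed)

    def test_stress_contrast_significant_in_both_groups(self):
        hits = 0
        for seed in range(200):
            df = self.cohort_frame(seed=seed)
            summary = rg.summarize_spsl(records_from_frame(df))
            ok = (
                summary.within_group[("control", "T1-T2")].significant
                and summary.within_group[("test", "T1-T2")].significant
            )
            hits += ok
        assert hits >= 190

    def test_identical_groups_show_no_between_difference(self):
        recs = [
            SPSLRecord(f"C{i}", "control", (2, 4, 2, 2)) for i in range(5)
        ] + [SPSLRecord(f"T{i}", "test", (2, 4, 2, 2)) for i in range(5)]
        summary = rg.summarize_spsl(recs)
        for t, res in summary.between_group.items():
            assert res.p_value == 1.0, t

    def test_summary_means_bounded_by_scale(self):
        df = self.cohort_frame(seed=3)
        summary = rg.summarize_spsl(records_from_frame(df))
        assert (summary.means.to_numpy() >= 1).all()
        assert (summary.means.to_numpy() <= 5).all()

    def test_single_group_rejected(self):
        recs = [SPSLRecord(f"C{i}", "control", (2, 4, 2, 2)) for i in range(5)]
        with pytest.raises(ValueError):
            rg.summarize_spsl(recs)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            SPSLRecord("S", "control", (0, 4, 2, 2))
        frame = spsl_frame([SPSLRecord("S", "control", (1, 5, 3, 2))])
        assert list(frame.columns) == ["subject_id", "group", "T1", "T2", "T3", "T4"]


class TestRGAtInstants:
    def test_constant_series_returns_constant(self):
        out = rg.rg_at_instants(np.full(480, 1.7), {"T1": 0, "T2": 300})
        assert out == {"T1": pytest.approx(1.7), "T2": pytest.approx(1.7)}

    def test_window_at_series_start_is_clipped(self):
        x = np.arange(480.0)
        out = rg.rg_at_instants(x, {"T1": 0})
        assert out["T1"] == pytest.approx(x[:15].mean())

    def test_ramp_value_matches_window_centre(self):
        x = 2.0 * np.arange(480.0) + 1.0
        out = rg.rg_at_instants(x, {"T3": 345})
        # centred [330, 360) window of an affine series averages to its midpoint
        assert out["T3"] == pytest.approx(x[330:360].mean())
        assert out["T3"] == pytest.approx(2.0 * 344.5 + 1.0)

    def test_instant_outside_series_rejected(self):
        with pytest.raises(ValueError):
            rg.rg_at_instants(np.zeros(480), {"T4": 500})

    def test_default_instants_follow_boundaries(self):
        b = {"RS1": (0, 30), "MIST_TASK": (120, 300), "RELAX": (300, 450)}
        inst = default_instant_epochs(b)
        assert inst == {"T1": 0, "T2": 300, "T3": 345, "T4": 450}


class TestCorrelateSPSLRG:
    def test_affine_positive_relation_gives_unit_pcc(self):
        spsl = np.array([2.0, 4.0, 2.0, 2.0])
        res = rg.correlate_spsl_rg(spsl, 0.1 * spsl + 0.2)
        assert res.pcc == pytest.approx(1.0)
        assert res.ci_low is None and res.ci_up is None

    def test_negative_slope_gives_minus_one(self):
        spsl = np.array([2.0, 4.0, 2.0, 2.0])
        res = rg.correlate_spsl_rg(spsl, -0.1 * spsl)
        assert res.pcc == pytest.approx(-1.0)

    def test_same_pattern_correlates_perfectly(self):
        res = rg.correlate_spsl_rg(
            np.array([2.0, 4.0, 2.0, 2.0]), np.array([0.3, 0.5, 0.3, 0.3])
        )
        assert res.pcc == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rg.correlate_spsl_rg(np.array([2.0, 2, 2, 2]), np.array([1.0, 2, 3, 4]))
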