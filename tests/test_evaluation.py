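import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drcbridge import (
    EvalPair,
    PairedComparison,
    bootstrap_ci,
    paired_t,
    pearson_r,
    performance_ratio,
    replicate_replicability,
)
from drcbridge import SimConfig, StudyDesign, simulate
from drcbridge.simulate import attenuation_oracle


class TestPearsonR:
    def test_perfect_positive_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r(EvalPair(x, 2 * x + 3)) == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        x = np.arange(10.0)
        assert pearson_r(EvalPair(x, -x)) == pytest.approx(-1.0)

    def test_hand_derived_three_point_value(self):
        r = pearson_r(EvalPair([1, 2, 3], [1, 2, 4]))
        assert r == pytest.approx(3.0 / np.sqrt(2 * 42 / 9), abs=1e-9)
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_matches_scipy_on_random_vectors(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        expected = stats.pearsonr(x, y).statistic
        assert pearson_r(EvalPair(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert pearson_r(EvalPair([1, 1, 1, 1], [1, 2, 3, 4])) is None

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.4, 5.0]
        pair = EvalPair(x, y)
        assert len(pair) == 4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance_and_antisymmetry(self, seed, slope, intercept):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson_r(EvalPair(x, y))
        r_affine = pearson_r(EvalPair(x, slope * y + intercept))
        assert r_affine == pytest.approx(r, abs=1e-9)
        assert pearson_r(EvalPair(x, -y)) == pytest.approx(-r, abs=1e-9)


class TestBootstrapCI:
    def test_perfectly_correlated_data_degenerate_interval(self, rng):
        x = rng.normal(size=100)
        lo, hi = bootstrap_ci(EvalPair(x, 3 * x), seed=0)
        assert lo == pytest.approx(1.0)
        assert hi == pytest.approx(1.0)

    def test_interval_brackets_subsample_median(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        pair = EvalPair(x, y)
        lo, hi = bootstrap_ci(pair, seed=1)
        assert lo <= pearson_r(pair) <= hi

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        pair = EvalPair(x, y)
        assert bootstrap_ci(pair, seed=7) == bootstrap_ci(pair, seed=7)
        assert bootstrap_ci(pair, seed=7) != bootstrap_ci(pair, seed=8)


class TestPairedT:
    def test_balanced_differences_give_zero_t(self):
        res = paired_t(PairedComparison([1.0, 0.0], [0.0, 1.0]))
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_identical_nonzero_differences_flagged(self):
        res = paired_t(PairedComparison([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]))
        assert res.zero_variance
        assert res.p == 0.0

    def test_hand_evaluated_statistic(self):
        # d = [0.1, 0.2, 0.3, 0.4]: t = 1/sqrt((4*0.30 - 1)/3) = 3.873
        m2 = np.zeros(4)
        m1 = np.array([0.1, 0.2, 0.3, 0.4])
        res = paired_t(PairedComparison(m1, m2))
        assert res.t == pytest.approx(3.872983, abs=1e-5)

    def test_matches_scipy_paired_ttest(self, rng):
        a = rng.normal(size=12)
        b = a + 0.3 + rng.normal(scale=0.5, size=12)
        res = paired_t(PairedComparison(a, b))
        expected = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(expected.statistic, abs=1e-9)
        assert res.p == pytest.approx(expected.pvalue, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8))
        fwd = paired_t(PairedComparison(a, b))
        rev = paired_t(PairedComparison(b, a))
        assert fwd.t == pytest.approx(-rev.t, abs=1e-9)
        assert fwd.p == pytest.approx(rev.p, abs=1e-9)


class TestPerformanceRatio:
    def test_identical_lists_give_unity(self):
        assert performance_ratio(PairedComparison([0.3, 0.4], [0.3, 0.4])) == 1.0

    def test_doubled_performance(self):
        assert performance_ratio(PairedComparison([0.6, 0.8], [0.3, 0.4])) == \
            pytest.approx(2.0)

    def test_mirrors_reported_ratio_style(self):
        # means 0.46 vs 0.25 -> 184%
        cmp = PairedComparison([0.46, 0.46], [0.25, 0.25])
        assert performance_ratio(cmp) == pytest.approx(1.84)

    def test_zero_denominator_undefined(self):
        assert performance_ratio(PairedComparison([1.0, 1.0], [1.0, -1.0])) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_reciprocity_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 1.0, size=6)
        b = rng.uniform(0.1, 1.0, size=6)
        pr = performance_ratio(PairedComparison(a, b))
        pr_inv = performance_ratio(PairedComparison(b, a))
        assert pr * pr_inv == pytest.approx(1.0, abs=1e-9)


class TestReplicateReplicability:
    def replicated_sim(self, **overrides):
        kwargs = dict(
            studies=(StudyDesign("A", n_doses=4, n_combinations=60,
                                 replicate_count=2),),
            n_drugs=10, n_cell_lines=5, seed=21,
        )
        kwargs.update(overrides)
        return simulate(SimConfig(**kwargs))

    def test_noiseless_replicates_perfectly_correlated(self):
        sim = self.replicated_sim(
            response_noise_sd=0.0, sensitivity_noise_sd=0.0,
            synergy_noise_sd=0.0, response_gain_sd=0.0, response_offset_sd=0.0)
        result = replicate_replicability(sim.studies[0], "CSS")
        assert result.r == pytest.approx(1.0)

    def test_ordered_pair_count(self):
        sim = self.replicated_sim()
        result = replicate_replicability(sim.studies[0], "CSS")
        # k = 2 replicates per key -> k(k-1) = 2 ordered pairs per key
        assert result.n_pairs == 2 * result.n_keys
        assert result.n_keys == 60

    def test_sensitivity_more_replicable_than_synergy(self):
        sim = self.replicated_sim()
        css = replicate_replicability(sim.studies[0], "CSS")
        bliss = replicate_replicability(sim.studies[0], "Bliss")
        assert css.r > bliss.r

    def test_insufficient_keys_undefined(self):
        sim = self.replicated_sim()
        ds = sim.studies[0]
        ds.combinations = ds.combinations[:4]  # 2 keys only
        result = replicate_replicability(ds, "CSS")
        assert result.r is None

    def test_matches_attenuation_oracle_at_scale(self):
        """Monte-Carlo replicate correlation agrees with the closed-form
        attenuation var(signal)/(var(signal)+sigma^2) within 3 SE."""
        config = SimConfig(
            studies=(StudyDesign("A", n_doses=3, n_combinations=2500,
                                 replicate_count=2),),
            n_drugs=40, n_cell_lines=20, seed=5,
        )
        sim = simulate(config)
        result = replicate_replicability(sim.studies[0], "Bliss")
        expected = attenuation_oracle(config, "Bliss")
        se = (1 - expected ** 2) / np.sqrt(result.n_pairs / 2)
        assert result.r == pytest.approx(expected, abs=3 * se)
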