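"""Decision mechanisms: Laplace sampler, private tests, baselines."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest, laplace

from dpchisq import (
    PrivateNull,
    build_table,
    critical_value,
    mc_indep,
    non_private_test,
    rand_chi,
    rand_chi_dist,
    rand_cell,
    randchidist_sensitivity,
    sample_laplace,
)
from dpchisq.exceptions import ConfigError
from dpchisq.mechanisms import _laplace

HUGE_EPS = 1e9  # noise scale ~0; private mechanisms reduce to the classical test


class TestLaplaceSampler:
    def test_deterministic_given_seed(self):
        a = sample_laplace(2.0, np.random.default_rng(42))
        b = sample_laplace(2.0, np.random.default_rng(42))
        assert a == b

    def test_moments(self):
        draws = _laplace(1.0, 10**6, np.random.default_rng(0))
        assert abs(draws.mean()) < 3 * np.sqrt(2 / 10**6)
        assert draws.var() == pytest.approx(2.0, rel=0.02)

    def test_distribution_not_rejected(self):
        draws = _laplace(3.0, 10**5, np.random.default_rng(1))
        stat = kstest(draws, laplace(scale=3.0).cdf)
        assert stat.pvalue > 0.01

    def test_scalar_wraps_vector_path(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        assert sample_laplace(1.5, rng1) == float(_laplace(1.5, None, rng2))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            sample_laplace(0.0, np.random.default_rng(0))


class TestRandChiDist:
    def test_zero_noise_limit_matches_non_private(self, example_table):
        out = rand_chi_dist(example_table, HUGE_EPS, 0.05, np.random.default_rng(2))
        ref = non_private_test(example_table, 0.05)
        assert out.decision == ref.decision == "fail_to_reject"
        assert out.noisy_statistic == pytest.approx(0.0102, abs=1e-3)
        assert out.threshold == pytest.approx(chi2.ppf(0.95, 1), abs=1e-3)

    def test_deterministic_given_seed(self, example_table):
        a = rand_chi_dist(example_table, 0.1, 0.05, np.random.default_rng(3))
        b = rand_chi_dist(example_table, 0.1, 0.05, np.random.default_rng(3))
        assert a == b

    def test_calibration_by_construction(self):
        # when the statistic is drawn exactly from chi2_v, the calibrated
        # threshold rejects with probability alpha
        v, delta, eps, alpha = 1, 4.0, 0.1, 0.05
        null = PrivateNull(v, delta, eps)
        t = critical_value(null, alpha)
        rng = np.random.default_rng(8)
        n = 10**5
        noisy = chi2.rvs(v, size=n, random_state=rng) + rng.laplace(0, null.scale, n)
        freq = np.mean(noisy >= t)
        assert abs(freq - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n)

    def test_decision_coherent_with_p_value(self, rng):
        epsilons = (0.05, 0.1, 1.0, 10.0)
        alphas = (0.005, 0.01, 0.05)
        for i in range(1000):
            counts = rng.integers(1, 40, size=(2, 2))
            table = build_table(counts)
            eps = epsilons[i % 4]
            alpha = alphas[i % 3]
            out = rand_chi_dist(table, eps, alpha, rng)
            if abs(out.p_value - alpha) > 1e-12:
                assert (out.p_value <= alpha) == out.rejected

    def test_threshold_dominance_in_epsilon(self, example_table):
        outs = [
            rand_chi_dist(example_table, eps, 0.05, np.random.default_rng(0))
            for eps in (0.01, 0.1, 1.0)
        ]
        assert outs[0].threshold >= outs[1].threshold >= outs[2].threshold

    def test_empirical_privacy_ratio_of_released_statistic(self):
        # neighboring tables (one unit moved within row 0, margins fixed);
        # the released noisy statistic's histogram ratio must respect e^eps
        d1, d2 = build_table([[3, 3], [2, 4]]), build_table([[4, 2], [2, 4]])
        eps = 1.0
        sens = randchidist_sensitivity(d1.row_margins, 2).value
        from dpchisq import chi_squared

        rng = np.random.default_rng(11)
        n = 10**6
        rel1 = chi_squared(d1).statistic + rng.laplace(0, sens / eps, n)
        rel2 = chi_squared(d2).statistic + rng.laplace(0, sens / eps, n)
        bins = np.linspace(-15, 20, 36)
        h1, _ = np.histogram(rel1, bins)
        h2, _ = np.histogram(rel2, bins)
        ok = (h1 >= 500) & (h2 >= 500)
        ratio = h1[ok] / h2[ok]
        bound = np.exp(eps) * 1.1
        assert np.all(ratio <= bound) and np.all(1 / ratio <= bound)


class TestRandChi:
    def test_threshold_is_classical_percentage_point(self, example_table):
        out = rand_chi(example_table, 0.1, 0.05, np.random.default_rng(4))
        assert out.threshold == pytest.approx(chi2.ppf(0.95, 1), rel=1e-12)

    def test_zero_noise_limit_matches_non_private(self, example_table):
        out = rand_chi(example_table, HUGE_EPS, 0.05, np.random.default_rng(4))
        assert out.decision == non_private_test(example_table, 0.05).decision


class TestRandCell:
    def test_zero_noise_limit_matches_non_private(self, example_table):
        out = rand_cell(example_table, HUGE_EPS, 0.05, np.random.default_rng(5))
        assert out.decision == non_private_test(example_table, 0.05).decision
        assert out.flag is None

    def test_small_noisy_cell_triggers_rule_of_thumb(self):
        # with negligible noise the cell of 4 stays below five
        table = build_table([[4, 30], [20, 25]])
        out = rand_cell(table, HUGE_EPS, 0.05, np.random.default_rng(6))
        assert out.decision == "fail_to_reject"
        assert out.flag == "rule_of_thumb"
        assert out.noisy_statistic is None

    def test_true_margin_variant(self, example_table):
        out = rand_cell(
            example_table,
            HUGE_EPS,
            0.05,
            np.random.default_rng(7),
            use_true_margins=True,
        )
        assert out.noisy_statistic == pytest.approx(0.0102, abs=1e-3)


class TestMcIndep:
    def test_small_sampled_cells_trigger_rule_of_thumb(self):
        # n = 12 across four cells: sampled reference tables are bound to
        # contain a cell below five
        table = build_table([[3, 3], [3, 3]])
        out = mc_indep(table, HUGE_EPS, 0.05, np.random.default_rng(8))
        assert out.decision == "fail_to_reject"
        assert out.flag == "rule_of_thumb"

    def test_rejects_extreme_association_without_noise(self):
        table = build_table([[50, 0], [0, 50]])
        out = mc_indep(
            table, HUGE_EPS, 0.05, np.random.default_rng(9), n_mc_tables=10**4
        )
        assert out.decision == "reject"

    def test_deterministic_given_seed(self, example_table):
        a = mc_indep(example_table, 0.1, 0.05, np.random.default_rng(10))
        b = mc_indep(example_table, 0.1, 0.05, np.random.default_rng(10))
        assert a == b

    def test_too_few_reference_tables_rejected(self, example_table):
        with pytest.raises(ConfigError):
            mc_indep(
                example_table, 0.1, 0.01, np.random.default_rng(0), n_mc_tables=50
            )


class TestNonPrivate:
    def test_example_table_not_significant(self, example_table):
        out = non_private_test(example_table, 0.05)
        assert out.decision == "fail_to_reject"
        assert out.p_value == pytest.approx(chi2.sf(0.010203040506, 1), rel=1e-6)

    def test_extreme_table_significant(self):
        assert non_private_test(build_table([[50, 0], [0, 50]]), 0.05).rejected

    def test_near_one_alpha_rejects_any_association(self, example_table):
        assert non_private_test(example_table, 0.9999).rejected

    def test_alpha_validated(self, example_table):
        with pytest.raises(ConfigError):
            non_private_test(example_table, 0.0)
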