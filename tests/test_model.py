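import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geomgof as gg

thetas = st.floats(min_value=0.01, max_value=0.99)


class TestPmfCdf:
    def test_pmf_examples(self):
        assert gg.pmf_vector(0.5, 1) == pytest.approx([0.5])
        assert gg.pmf_vector(0.5, 3) == pytest.approx([0.5, 0.25, 0.125])
        assert gg.pmf_vector(0.512, 2) == pytest.approx([0.512, 0.249856])

    def test_cdf_examples(self):
        assert gg.cdf_vector(0.5, 4) == pytest.approx([0.5, 0.75, 0.875, 0.9375])
        assert gg.cdf_vector(0.5, 1) == pytest.approx([0.5])

    @given(theta=thetas, k=st.integers(1, 60))
    @settings(derandomize=True, max_examples=50)
    def test_pmf_sums_to_truncated_mass(self, theta, k):
        # geometric series closed form: sum p_i = 1 - (1-theta)**k
        assert gg.pmf_vector(theta, k).sum() == pytest.approx(
            1.0 - (1.0 - theta) ** k, abs=1e-12
        )

    @given(theta=thetas, k=st.integers(1, 60))
    @settings(derandomize=True, max_examples=50)
    def test_cdf_consistency_and_monotonicity(self, theta, k):
        H = gg.cdf_vector(theta, k)
        sf = gg.sf_vector(theta, k)
        assert H[-1] == pytest.approx(gg.pmf_vector(theta, k).sum(), abs=1e-12)
        # monotonicity checked on the survival scale, where the geometric
        # decay never saturates the floating-point representation
        assert np.all(np.diff(sf) < 0) and np.all(sf > 0)
        assert 0 < H[0] and np.all(np.diff(H) >= 0)
        assert sf == pytest.approx(1.0 - H, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_theta_rejected(self, bad):
        with pytest.raises(ValueError, match="theta"):
            gg.pmf_vector(bad, 3)


class TestScore:
    def test_closed_form_example(self):
        # d/dtheta of (1-theta)**(j-1)*theta at theta=0.5: b2 = 1 - 2*0.5 = 0
        assert gg.score_vector(0.5, 3) == pytest.approx([1.0, 0.0, -0.25])

    @given(theta=thetas)
    @settings(derandomize=True, max_examples=30)
    def test_first_entry_is_one(self, theta):
        assert gg.score_vector(theta, 5)[0] == pytest.approx(1.0)

    @given(theta=thetas)
    @settings(derandomize=True, max_examples=30)
    def test_matches_numerical_derivative(self, theta):
        h = 1e-6 * min(theta, 1 - theta)
        numeric = (gg.pmf_vector(theta + h, 8) - gg.pmf_vector(theta - h, 8)) / (2 * h)
        assert gg.score_vector(theta, 8) == pytest.approx(numeric, abs=1e-6)

    @pytest.mark.parametrize("theta", [0.1, 0.5, 0.9])
    def test_fisher_information_limit(self, theta):
        # sum b_j**2 / p_j converges (from below) to 1/(theta**2 (1-theta));
        # k deep enough for convergence yet shy of pmf underflow
        k = gg.truncation_floor(theta, 1e-200)
        b = gg.score_vector(theta, k)
        p = gg.pmf_vector(theta, k)
        partial = np.cumsum(b * b / p)
        assert np.all(np.diff(partial) >= -1e-14)
        assert partial[-1] == pytest.approx(gg.fisher_information(theta), abs=1e-6)
        if theta == 0.5:
            assert partial[199] == pytest.approx(8.0, abs=1e-6)


class TestMle:
    def test_market_estimate(self):
        assert round(gg.mle_theta(gg.load_example("nasdaq")), 3) == 0.512

    def test_hand_example(self, toy_table):
        assert gg.mle_theta(toy_table) == pytest.approx(0.5)

    def test_all_ones_is_degenerate(self):
        table = gg.FrequencyTable.from_counts({1: 10})
        with pytest.raises(gg.DegenerateSampleError):
            gg.mle_theta(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            gg.FrequencyTable.from_counts({})

    @pytest.mark.parametrize("theta", [0.1, 0.5, 0.9])
    def test_parameter_recovery(self, theta):
        rng = np.random.default_rng(2024)
        x = gg.sample_geometric(rng, theta, 100_000)
        est = gg.mle_theta(gg.FrequencyTable.from_sample(x))
        assert abs(est - theta) < 0.01


class TestWaldCI:
    @pytest.mark.parametrize(
        "theta,n,expected",
        [(0.512, 1032, (0.490, 0.534)), (0.476, 958, (0.454, 0.498))],
    )
    def test_market_intervals(self, theta, n, expected):
        lo, hi = gg.wald_ci(theta, n, 0.95)
        assert (round(lo, 3), round(hi, 3)) == expected

    def test_small_level_collapses_to_estimate(self):
        lo, hi = gg.wald_ci(0.4, 100, 1e-12)
        assert lo == pytest.approx(0.4, abs=1e-6)
        assert hi == pytest.approx(0.4, abs=1e-6)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            gg.wald_ci(1.0, 100, 0.95)
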