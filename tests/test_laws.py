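"""Closed-form reference laws and the master-equation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats as sps

import clonesim as cs
from clonesim.laws import TwoStateGIAParams, master_equation_oracle, two_state_gia_density


def _sup_cdf_diff(law_a, law_b, grid):
    return float(np.abs(law_a.cdf(grid) - law_b.cdf(grid)).max())


class TestTwoStateGIADensity:
    @pytest.mark.parametrize("lhat1,lhat2", [(20.0, 0.5), (50.0, 0.0), (5.0, 0.9)])
    def test_normalisation(self, lhat1, lhat2):
        p = TwoStateGIAParams(lhat1, lhat2)
        total, _ = integrate.quad(lambda x: two_state_gia_density(x, p), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalisation_defect_at_small_mean(self):
        """The law is asymptotic in the stationary mean: at mean 10 the
        printed closed form integrates to 1 only up to O(1e-4)."""
        p = TwoStateGIAParams(5.0, 0.5)
        total, _ = integrate.quad(lambda x: two_state_gia_density(x, p), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_unit_mean_in_fast_division_regime(self):
        p = TwoStateGIAParams(50.0, 0.5)
        m1, _ = integrate.quad(lambda x: x * two_state_gia_density(x, p), 0, np.inf, limit=200)
        assert m1 == pytest.approx(1.0, abs=0.02)

    def test_exponential_limit(self):
        """As both dimensionless rates approach one the law degenerates to the
        unit-mean Exponential (the GPA universal law)."""
        law = cs.two_state_gia_law(TwoStateGIAParams(1.0, 0.99))
        grid = np.linspace(0.001, 10, 2000)
        assert _sup_cdf_diff(law, cs.exp_unit_mean(), grid) <= 0.05

    def test_normal_limit(self):
        law = cs.two_state_gia_law(TwoStateGIAParams(100.0, 0.3))
        limit = cs.normal_limit(TwoStateGIAParams(100.0, 0.3))
        assert limit.var == pytest.approx(0.01)
        grid = np.linspace(0.5, 1.5, 2000)
        assert _sup_cdf_diff(law, limit, grid) <= 0.02

    def test_peaked_versus_monotone_shapes(self):
        """Fast renewing division gives a peaked (interior-mode) density;
        slow division loses the peak (monotone decreasing)."""
        x = np.linspace(0.01, 4.0, 800)
        peaked = two_state_gia_density(x, TwoStateGIAParams(20.0, 0.5))
        imax = int(np.argmax(peaked))
        assert 0 < imax < len(x) - 1
        flat = two_state_gia_density(x, TwoStateGIAParams(0.2, 0.5))
        assert (np.diff(flat) < 0).all()

    def test_large_rate_no_overflow(self):
        val = two_state_gia_density(1.0, TwoStateGIAParams(500.0, 0.2))
        assert np.isfinite(val) and val > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TwoStateGIAParams(1.0, 1.0)
        with pytest.raises(ValueError):
            TwoStateGIAParams(0.0, 0.5)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.floats(0.3, 60.0),
        st.floats(0.0, 0.9),
        st.integers(0, 1000),
    )
    def test_cdf_is_monotone_and_bounded(self, lhat1, lhat2, seed):
        law = cs.two_state_gia_law(TwoStateGIAParams(lhat1, lhat2))
        grid = np.sort(np.random.default_rng(seed).uniform(0, 20, 50))
        c = law.cdf(grid)
        assert (np.diff(c) >= 0).all()
        assert (c >= 0).all() and (c <= 1).all()


class TestExactStationaryLaw:
    def test_poisson_case(self):
        law = cs.gia0_stationary_law(1.0, 0.0, 1.0)
        assert law.pmf(0) == pytest.approx(np.exp(-1.0))
        assert law.mean == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "lam1,lam2,gamma", [(1.0, 0.5, 1.0), (1.0, 1.0, 2.0), (2.5, 0.3, 0.9)]
    )
    def test_mean_is_closed_form(self, lam1, lam2, gamma):
        law = cs.gia0_stationary_law(lam1, lam2, gamma)
        n = np.arange(0, 5000)
        mass = law.pmf(n)
        assert mass.sum() == pytest.approx(1.0, abs=1e-10)
        assert float(n @ mass) == pytest.approx(lam1 / (gamma - lam2), abs=1e-10)

    def test_supercritical_committed_rejected(self):
        with pytest.raises(ValueError, match="lambda2 < gamma"):
            cs.gia0_stationary_law(1.0, 2.0, 1.0)

    @pytest.mark.parametrize("nbar2,bound", [(10.0, 0.12), (50.0, 0.03)])
    def test_rescaled_exact_law_converges_to_closed_form(self, nbar2, bound):
        """The rescaled exact stationary law approaches the continuous
        closed form as the stationary mean grows."""
        lhat2 = 0.5
        lhat1 = nbar2 * (1.0 - lhat2)
        law = cs.gia0_stationary_law(lhat1, lhat2, 1.0)
        n = np.arange(0, int(nbar2 * 8))
        exact_cdf = np.cumsum(law.pmf(n))
        closed = cs.two_state_gia_law(TwoStateGIAParams(lhat1, lhat2))
        diff = np.abs(exact_cdf - closed.cdf((n + 0.5) / nbar2)).max()
        assert diff <= bound


class TestMasterEquationOracle:
    def test_ia_total_size_is_shifted_poisson(self):
        """IA at t=20: one conserved stem cell plus a Poisson number of
        differentiated cells with mean (lam/gamma)(1 - e^{-gamma t})."""
        ia = cs.canonical("IA", lam=1.0, gamma=1.0)
        sizes, probs = master_equation_oracle(ia, "S", t=20.0)
        mu = 1.0 - np.exp(-20.0)
        expected = sps.poisson(mu).pmf(sizes - 1)
        expected[sizes - 1 < 0] = 0.0
        assert np.abs(probs - expected).sum() <= 1e-6

    def test_matches_exact_stationary_law(self, gia0_model):
        sizes, probs = master_equation_oracle(gia0_model, "X1", t=30.0)
        law = cs.gia0_stationary_law(1.0, 0.5, 1.0)
        stat = law.pmf(sizes - 1)  # shift by the conserved renewing cell
        stat[sizes - 1 < 0] = 0.0
        assert 0.5 * np.abs(probs - stat / stat.sum()).sum() <= 1e-4

    def test_matches_gillespie_transient(self, gia0_model):
        """Oracle and simulator agree mid-transient (t=5), KS <= 0.01."""
        sizes, probs = master_equation_oracle(gia0_model, "X1", t=5.0)
        ens = cs.simulate_ensemble(
            gia0_model, 30_000, "X1", cs.StoppingRule("fixed_time", t_max=5.0), seed=21
        )
        total = ens.total[:, -1]
        cdf = np.cumsum(probs)
        ecdf = np.searchsorted(np.sort(total), sizes, side="right") / total.size
        assert np.abs(ecdf - cdf).max() <= 0.01

    def test_too_many_states_rejected(self):
        model, _ = cs.random_homeostatic(cs.GeneratorConfig(seed=1, class_target="GPA", n_states=5))
        with pytest.raises(ValueError, match="m <= 3"):
            master_equation_oracle(model, model.states[0], t=1.0)
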