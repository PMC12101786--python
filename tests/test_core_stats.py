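"""Exact transient/steady-state statistics: recursion, closed forms, moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quantalkit import core_stats as cs
from quantalkit.params import QuantalSizeModel, Schedule, SynapseParams

probs = st.floats(min_value=0.01, max_value=0.99)


class TestOccupancyRecursion:
    def test_saturated_sites_stay_full(self):
        # full refill + full release keeps every site occupied before each AP
        params = SynapseParams(M=10, p1=1.0, pr=1.0, pd=1.0, pu=0.0)
        series = cs.occupancy_recursion(params, 20)
        assert np.allclose(series.p, 1.0)

    def test_converges_to_fixed_point(self):
        params = SynapseParams(M=10, p1=1.0, pr=0.15, pd=0.05, pu=0.0)
        series = cs.occupancy_recursion(params, 500)
        expected = 0.05 / (0.05 + 0.15 - 0.0075)
        assert series.p[-1] == pytest.approx(expected, abs=1e-12)
        assert series.p[-1] == pytest.approx(0.2597, abs=5e-4)

    def test_facilitation_then_depression(self):
        # ramping release probability produces a rising mean QC over the
        # first stimuli before depletion takes over
        params = SynapseParams(
            M=200, p1=1.0, pr=Schedule((0.15, 0.2, 0.25), 0.3), pd=0.02, pu=0.0
        )
        series = cs.occupancy_recursion(params, 30)
        m = series.mean_qc
        assert m[0] < m[1] < m[2]
        assert m[-1] < m[2]

    def test_mean_and_fano_identities(self):
        # FF_i = 1 - <b_i>/M holds exactly for arbitrary schedules
        params = SynapseParams(
            M=150, p1=0.8,
            pr=Schedule((0.1, 0.9, 0.4), 0.6),
            pd=Schedule((0.9, 0.2), 0.5),
            pu=Schedule((0.05,), 0.1),
        )
        series = cs.occupancy_recursion(params, 40)
        assert np.allclose(series.fano + series.mean_qc / params.M, 1.0, atol=1e-12)

    def test_invalid_schedule_names_offender(self):
        with pytest.raises(ValueError, match=r"pd\[2\]"):
            SynapseParams(M=10, pr=0.5, pd=[0.3, 1.7, 0.2], pu=0.0)

    def test_requires_at_least_one_stimulus(self):
        with pytest.raises(ValueError, match="n_stimuli"):
            cs.occupancy_recursion(SynapseParams(), 0)


class TestClosedForm:
    def test_first_stimulus_returns_initial_occupancy(self):
        assert cs.occupancy_closed_form(1.0, 0.15, 0.0, 0.05, 1) == pytest.approx(1.0)

    def test_limit_is_fixed_point(self):
        assert cs.occupancy_closed_form(1.0, 0.15, 0.0, 0.05, 10_000) == pytest.approx(
            0.2597, abs=5e-4
        )

    def test_matches_recursion_for_random_constants(self, rng):
        # closed form and iterated recursion agree to 1e-12 at every stimulus
        for _ in range(100):
            p1, pr, pu, pd = rng.random(4)
            pu = min(pu, 1 - pd)  # keep pd + pu <= 1 as in a two-state chain
            params = SynapseParams(M=5, p1=p1, pr=pr, pd=pd, pu=pu)
            series = cs.occupancy_recursion(params, 50)
            closed = [cs.occupancy_closed_form(p1, pr, pu, pd, i) for i in range(1, 51)]
            assert np.allclose(series.p, closed, atol=1e-12)

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            cs.occupancy_closed_form(0.5, 0.0, 0.0, 0.0, 5)

    @given(p1=probs, pr=probs, pd=probs)
    @settings(max_examples=50, deadline=None)
    def test_geometric_convergence(self, p1, pr, pd):
        # |p_i - pbar| <= |p_1 - pbar| * |lam|**(i-1), lam = (1-pr)(1-pd)
        pbar = cs.steady_state_occupancy(pr, 0.0, pd)
        lam = abs((1 - pr) * (1 - pd))
        params = SynapseParams(M=5, p1=p1, pr=pr, pd=pd, pu=0.0)
        p = cs.occupancy_recursion(params, 30).p
        bound = abs(p1 - pbar) * lam ** np.arange(30)
        assert np.all(np.abs(p - pbar) <= bound + 1e-12)


class TestQcPmf:
    def test_first_stimulus_full_pool(self):
        params = SynapseParams(M=100, p1=1.0, pr=0.5, pd=0.4, pu=0.1)
        pmf = cs.qc_pmf(params, 1)
        j = np.arange(101)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf * j).sum() == pytest.approx(50.0, abs=1e-9)
        var = (pmf * j**2).sum() - 50.0**2
        assert var / 50.0 == pytest.approx(0.5, abs=1e-9)

    def test_zero_release_is_point_mass(self):
        params = SynapseParams(M=20, p1=1.0, pr=0.0, pd=0.5, pu=0.0)
        pmf = cs.qc_pmf(params, 3)
        assert pmf[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("i", [1, 3, 10])
    def test_moments_match_occupancy_series(self, i):
        params = SynapseParams(M=30, p1=0.9, pr=0.3, pd=0.4, pu=0.1)
        series = cs.occupancy_recursion(params, i)
        pmf = cs.qc_pmf(params, i)
        j = np.arange(31)
        mean = (pmf * j).sum()
        var = (pmf * j**2).sum() - mean**2
        assert mean == pytest.approx(series.mean_qc[i - 1], abs=1e-10)
        assert var / mean == pytest.approx(series.fano[i - 1], abs=1e-10)


class TestSteadyState:
    def test_occupancy_values(self):
        assert cs.steady_state_occupancy(0.15, 0.0, 0.05) == pytest.approx(0.2597, abs=5e-4)
        assert cs.steady_state_occupancy(0.53, 0.0, 0.93) == pytest.approx(0.96, abs=5e-3)
        assert cs.steady_state_occupancy(0.4, 0.0, 0.9999) == pytest.approx(1.0, abs=1e-3)

    def test_fano_values(self):
        assert cs.steady_state_fano(1e-6, 0.0, 0.5) == pytest.approx(1.0, abs=1e-5)
        assert cs.steady_state_fano(0.93, 0.0, 0.53) == pytest.approx(0.490, abs=1e-3)
        # near-saturation approximation FF ~ 2 - pd - pr
        assert cs.steady_state_fano(0.95, 0.0, 0.95) == pytest.approx(0.10, abs=0.02)

    @given(pr=probs, pd=probs)
    @settings(max_examples=60, deadline=None)
    def test_fano_and_corr_swap_symmetric_without_undocking(self, pr, pd):
        assert cs.steady_state_fano(pr, 0.0, pd) == pytest.approx(
            cs.steady_state_fano(pd, 0.0, pr), abs=1e-14
        )
        assert cs.steady_state_corr(pr, 0.0, pd) == pytest.approx(
            cs.steady_state_corr(pd, 0.0, pr), abs=1e-14
        )

    def test_corr_zero_at_full_release(self):
        assert cs.steady_state_corr(1.0, 0.0, 0.3) == 0.0

    def test_corr_global_minimum(self):
        assert cs.steady_state_corr(0.5, 0.0, 0.5) == pytest.approx(-0.125, abs=1e-14)

    def test_corr_bounds_on_grid(self):
        vals = np.arange(0.02, 1.0, 0.02)
        rho = np.array([[cs.steady_state_corr(a, 0.0, b) for b in vals] for a in vals])
        assert np.all(rho <= 0.0)
        assert np.all(rho >= -0.125 - 1e-12)
        amin = np.unravel_index(rho.argmin(), rho.shape)
        assert vals[amin[0]] == pytest.approx(0.5)
        assert vals[amin[1]] == pytest.approx(0.5)

    def test_rho_argmin_pr(self):
        assert cs.rho_argmin_pr(0.5) == pytest.approx(0.5)
        assert cs.rho_argmin_pr(0.8) == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert cs.rho_argmin_pr(1e-6) == pytest.approx(0.0, abs=1e-2)
        with pytest.raises(ValueError):
            cs.rho_argmin_pr(1.0)

    def test_rho_argmin_is_grid_minimizer(self):
        pd = 0.8
        pr_star = cs.rho_argmin_pr(pd)
        grid = np.arange(0.01, 1.0, 0.01)
        vals = [cs.steady_state_corr(pr, 0.0, pd) for pr in grid]
        assert abs(grid[int(np.argmin(vals))] - pr_star) <= 0.01
        # local-minimum property
        eps = 1e-4
        assert cs.steady_state_corr(pr_star, 0.0, pd) <= cs.steady_state_corr(
            pr_star + eps, 0.0, pd
        )
        assert cs.steady_state_corr(pr_star, 0.0, pd) <= cs.steady_state_corr(
            pr_star - eps, 0.0, pd
        )

    def test_lag_corr_decays_geometrically(self):
        rho1 = cs.steady_state_corr(0.3, 0.1, 0.4, lag=1)
        lam = (1 - 0.3) * (1 - 0.1 - 0.4)
        for lag in (2, 3, 5):
            assert cs.steady_state_corr(0.3, 0.1, 0.4, lag=lag) == pytest.approx(
                rho1 * lam ** (lag - 1), abs=1e-14
            )

    def test_normalized_depression(self):
        # constant pr, full initial occupancy: depression equals pbar
        params = SynapseParams(M=10, p1=1.0, pr=0.53, pd=0.93, pu=0.0)
        assert cs.normalized_depression(params) == pytest.approx(0.96, abs=5e-3)
        near_one = SynapseParams(M=10, p1=1.0, pr=0.3, pd=0.9999, pu=0.0)
        assert cs.normalized_depression(near_one) == pytest.approx(1.0, abs=1e-3)
        near_zero = SynapseParams(M=10, p1=1.0, pr=0.3, pd=1e-6, pu=0.0)
        assert cs.normalized_depression(near_zero) == pytest.approx(0.0, abs=1e-4)
        with pytest.raises(ValueError, match="depression undefined"):
            cs.normalized_depression(SynapseParams(M=10, p1=0.0, pr=0.5, pd=0.5))

    def test_fano_lower_bounds(self, rng):
        assert cs.fano_lower_bounds(1.0) == (0.0, 0.0)
        assert cs.fano_lower_bounds(0.5) == (0.5, 0.5)
        for _ in range(50):
            pr, pd = rng.uniform(0.05, 0.95, 2)
            ff = cs.steady_state_fano(pr, 0.0, pd)
            pr_min, pd_min = cs.fano_lower_bounds(ff)
            assert pr >= pr_min - 1e-12
            assert pd >= pd_min - 1e-12

    def test_monotone_coupling_mean_vs_fano(self):
        # at equal M and stimulus index, the parameter set with the larger
        # mean QC always has the smaller Fano factor
        a = cs.occupancy_recursion(SynapseParams(M=200, p1=1, pr=0.15, pd=0.3), 25)
        b = cs.occupancy_recursion(SynapseParams(M=200, p1=1, pr=0.15, pd=0.05), 25)
        larger = a.mean_qc > b.mean_qc
        assert np.all(a.fano[larger] < b.fano[larger])


class TestEvokedStats:
    def test_degenerate_quantal_size_is_identity(self):
        ss = cs.SteadyStateStats(p_bar=0.5, ff=0.37, rho=-0.05)
        ff_e, rho_e = cs.evoked_stats(ss, QuantalSizeModel(c_mean=1.0, cv_q=0.0))
        assert ff_e == pytest.approx(0.37)
        assert rho_e == pytest.approx(-0.05)

    def test_closed_form_example(self):
        ss = cs.SteadyStateStats(p_bar=0.5, ff=0.5, rho=-0.035)
        ff_e, rho_e = cs.evoked_stats(ss, QuantalSizeModel(c_mean=22.0, cv_q=0.3))
        assert ff_e == pytest.approx(22 * 0.59, abs=1e-9)
        assert rho_e == pytest.approx(-0.035 * 0.5 / 0.59, abs=1e-9)

    def test_invalid_quantal_model(self):
        with pytest.raises(ValueError):
            QuantalSizeModel(c_mean=-1.0, cv_q=0.1)
        with pytest.raises(ValueError):
            QuantalSizeModel(c_mean=22.0, cv_q=-0.1)
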