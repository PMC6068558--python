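import math

import numpy as np
import pytest

from radarvitals import (
    OptimizerSettings,
    ParameterBounds,
    PhysioParams,
    add_awgn,
    baseband_iq,
    cost,
    estimate_ga,
    estimate_lsm,
    estimate_pso,
    estimation_error,
)
from radarvitals.estimation import CostEvaluator, PSOState


def point_bounds(p: PhysioParams) -> ParameterBounds:
    x = p.to_array()
    return ParameterBounds(lb=x.copy(), ub=x.copy(), name="point")


class TestCost:
    def test_zero_at_truth(self, ambiguity_params, ambiguity_signal, cfg):
        assert cost(ambiguity_params, ambiguity_signal, cfg, "time") < 1e-12
        assert cost(ambiguity_params, ambiguity_signal, cfg, "frequency") < 1e-12

    def test_phase_periodicity(self, ambiguity_params, ambiguity_signal, cfg):
        import dataclasses

        shifted = dataclasses.replace(
            ambiguity_params,
            phi_r=ambiguity_params.phi_r + 2 * math.pi,
            psi=ambiguity_params.psi - 2 * math.pi,
        )
        a = cost(ambiguity_params, ambiguity_signal, cfg, "time")
        b = cost(shifted, ambiguity_signal, cfg, "time")
        assert b == pytest.approx(a, abs=1e-9)

    def test_time_frequency_asymmetry_under_ambiguity(self, ambiguity_params, cfg):
        """Shifting phi_h by pi changes the time-domain fit visibly, while
        the magnitude-spectrum cost is far less sensitive — the documented
        asymmetry between the two domains under exact ambiguity."""
        import dataclasses

        sig = baseband_iq(ambiguity_params, cfg)
        shifted = dataclasses.replace(
            ambiguity_params, phi_h=ambiguity_params.phi_h + math.pi
        )
        t_cost = cost(shifted, sig, cfg, "time")
        f_cost = cost(shifted, sig, cfg, "frequency")
        assert t_cost > 1e-2
        assert f_cost < t_cost

    def test_zero_signal_rejected(self, cfg):
        from radarvitals import IQSignal

        zero = IQSignal(sample_rate=100.0, i=np.zeros(1000), q=np.zeros(1000))
        with pytest.raises(ValueError):
            cost(PhysioParams(mr=1, mh=0.1, fr=0.3, fh=1.2), zero, cfg)

    def test_vectorized_evaluator_matches_scalar(self, ambiguity_signal, cfg, rng):
        bounds = ParameterBounds.rest_narrow()
        xs = bounds.sample(rng, 8)
        for domain in ("time", "frequency"):
            ev = CostEvaluator(ambiguity_signal, cfg, domain)
            batch = ev(xs)
            scalar = [cost(x, ambiguity_signal, cfg, domain) for x in xs]
            assert np.allclose(batch, scalar, rtol=1e-3, atol=1e-5)


class TestLSM:
    def test_starting_at_truth_stays_there(self, ambiguity_params, ambiguity_signal, cfg):
        res = estimate_lsm(
            ambiguity_signal,
            cfg,
            ParameterBounds.rest_narrow(),
            OptimizerSettings(seed=0),
            x0=ambiguity_params.to_array(),
        )
        assert res.final_cost < 1e-6
        assert estimation_error(ambiguity_params, res.params, "fh").value < 0.01

    def test_point_bounds_return_that_point(self, ambiguity_params, ambiguity_signal, cfg):
        res = estimate_lsm(
            ambiguity_signal, cfg, point_bounds(ambiguity_params), OptimizerSettings(seed=3)
        )
        assert np.allclose(res.params.to_array(), ambiguity_params.canonical().to_array())

    def test_seeded_determinism(self, ambiguity_signal, cfg):
        r1 = estimate_lsm(ambiguity_signal, cfg, settings=OptimizerSettings(seed=5))
        r2 = estimate_lsm(ambiguity_signal, cfg, settings=OptimizerSettings(seed=5))
        assert r1.params == r2.params and r1.final_cost == r2.final_cost


class TestGA:
    def test_recovers_truth_noiseless(self, ambiguity_params, ambiguity_signal, cfg):
        res = estimate_ga(
            ambiguity_signal, cfg, ParameterBounds.rest_narrow(), OptimizerSettings(seed=11)
        )
        assert res.final_cost <= 1e-3
        assert estimation_error(ambiguity_params, res.params, "fh").value < 2.0

    def test_degenerate_population_is_stationary(self, ambiguity_params, ambiguity_signal, cfg):
        """Point bounds + zero mutation: every generation is identical and the
        best cost equals the cost of that single point (elitism floor)."""
        res = estimate_ga(
            ambiguity_signal,
            cfg,
            point_bounds(ambiguity_params),
            OptimizerSettings(seed=2, mutation_rate=0.0, max_evaluations=2000),
        )
        expected = cost(ambiguity_params, ambiguity_signal, cfg, "time")
        assert res.final_cost == pytest.approx(expected, abs=1e-6)

    def test_seeded_determinism(self, ambiguity_signal, cfg):
        st = OptimizerSettings(seed=7, max_evaluations=4000)
        r1 = estimate_ga(ambiguity_signal, cfg, settings=st)
        r2 = estimate_ga(ambiguity_signal, cfg, settings=st)
        assert r1.params == r2.params and r1.final_cost == r2.final_cost


class TestPSO:
    def test_recovers_truth_noiseless(self, ambiguity_params, ambiguity_signal, cfg):
        res = estimate_pso(
            ambiguity_signal, cfg, ParameterBounds.rest_narrow(), OptimizerSettings(seed=13)
        )
        assert res.final_cost <= 1e-3
        assert estimation_error(ambiguity_params, res.params, "fh").value < 2.0

    def test_point_swarm_returns_truth(self, ambiguity_params, ambiguity_signal, cfg):
        res = estimate_pso(
            ambiguity_signal,
            cfg,
            point_bounds(ambiguity_params),
            OptimizerSettings(seed=1, population_size=2, max_evaluations=200),
        )
        assert np.allclose(res.params.to_array(), ambiguity_params.canonical().to_array())
        # float32 batch evaluation leaves a ~1e-6 cost floor at the optimum
        assert res.final_cost < 1e-4

    def test_seeded_determinism(self, ambiguity_signal, cfg):
        st = OptimizerSettings(seed=21, max_evaluations=6000)
        r1 = estimate_pso(ambiguity_signal, cfg, settings=st)
        r2 = estimate_pso(ambiguity_signal, cfg, settings=st)
        assert r1.params == r2.params and r1.final_cost == r2.final_cost

    def test_best_cost_is_monotone(self, ambiguity_signal, cfg, rng):
        ev = CostEvaluator(ambiguity_signal, cfg, "time")
        state = PSOState(ev, ParameterBounds.rest_narrow(), 40, rng, 50)
        history = [state.gbest_cost] + [state.step() for _ in range(50)]
        assert all(b <= a + 1e-15 for a, b in zip(history, history[1:]))

    def test_respiration_rate_recovery_is_reliable(self, cfg):
        """fr is recovered within 2% across seeded noiseless runs."""
        ok = 0
        runs = 15
        for k in range(runs):
            rng = np.random.default_rng(500 + k)
            p = PhysioParams(
                mr=1.0, mh=0.08, fr=0.3, fh=1.2,
                phi_r=rng.uniform(0, 2 * math.pi),
                phi_h=rng.uniform(0, 2 * math.pi),
                psi=rng.uniform(0, 2 * math.pi),
            )
            sig = baseband_iq(p, cfg)
            res = estimate_pso(
                sig, cfg, ParameterBounds.rest_narrow(), OptimizerSettings(seed=900 + k)
            )
            if estimation_error(p, res.params, "fr").value < 2.0:
                ok += 1
        assert ok >= runs - 1


class TestGridSearchOracle:
    def test_pso_matches_exhaustive_grid_on_rate_plane(self, cfg):
        """Restricting to (fr, fh) with everything else at truth, the PSO
        optimum agrees with a brute-force grid search (step df/10) to
        within one grid step."""
        df10 = cfg.freq_resolution / 10.0
        p = PhysioParams(mr=1.0, mh=0.08, fr=0.31, fh=1.23, phi_r=0.8, phi_h=2.0, psi=1.1)
        sig = add_awgn(baseband_iq(p, cfg), 10.0, seed=8)
        x = p.to_array()
        lb, ub = x.copy(), x.copy()
        lb[2], ub[2] = 12 / 60, 25 / 60
        lb[3], ub[3] = 60 / 60, 100 / 60
        bounds = ParameterBounds(lb=lb, ub=ub, name="rates_only")

        ev = CostEvaluator(sig, cfg, "time")
        frs = np.arange(lb[2], ub[2] + df10 / 2, df10)
        fhs = np.arange(lb[3], ub[3] + df10 / 2, df10)
        grid = np.array([x.copy() for _ in range(frs.size * fhs.size)])
        mesh = np.array(np.meshgrid(frs, fhs, indexing="ij")).reshape(2, -1).T
        grid[:, 2], grid[:, 3] = mesh[:, 0], mesh[:, 1]
        costs = ev(grid)
        gbest = grid[np.argmin(costs)]

        hits = 0
        runs = 12
        for k in range(runs):
            res = estimate_pso(
                sig, cfg, bounds,
                OptimizerSettings(seed=3000 + k, population_size=50, max_evaluations=20000),
            )
            if (
                abs(res.params.fr - gbest[2]) <= df10
                and abs(res.params.fh - gbest[3]) <= df10
            ):
                hits += 1
        assert hits >= runs - 1


class TestErrorMetric:
    def test_exact_match_is_zero(self):
        p = PhysioParams(mr=1, mh=0.1, fr=0.3, fh=1.2)
        assert estimation_error(p, p, "fh").value == 0.0

    def test_ten_percent_example(self):
        actual = PhysioParams(mr=1, mh=0.1, fr=0.3, fh=72 / 60)
        est = PhysioParams(mr=1, mh=0.1, fr=0.3, fh=64.8 / 60)
        e = estimation_error(actual, est, "fh")
        assert e.value == pytest.approx(10.0)
        assert not e.absolute

    def test_zero_actual_falls_back_to_absolute(self):
        actual = PhysioParams(mr=0.0, mh=0.3, fr=0.3, fh=1.2)
        est = PhysioParams(mr=0.15, mh=0.3, fr=0.3, fh=1.2)
        e = estimation_error(actual, est, "mr")
        assert e.absolute
        assert e.value == pytest.approx(0.15)

    def test_unknown_component_raises(self):
        p = PhysioParams(mr=1, mh=0.1, fr=0.3, fh=1.2)
        with pytest.raises(KeyError):
            estimation_error(p, p, "heart_rate")


class TestBounds:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterBounds(lb=np.ones(7), ub=np.zeros(7))

    def test_presets_are_ordered_and_in_hz(self):
        b = ParameterBounds.rest_narrow()
        assert b.lb[2] == pytest.approx(12 / 60) and b.ub[3] == pytest.approx(100 / 60)
        wide = ParameterBounds.full_scale()
        rest, sport = ParameterBounds.at_rest(), ParameterBounds.after_sport()
        assert wide.lb[2] == rest.lb[2] and wide.ub[2] == sport.ub[2]
        assert wide.lb[3] == rest.lb[3] and wide.ub[3] == sport.ub[3]

    def test_sampling_stays_inside(self, rng):
        b = ParameterBounds.at_rest()
        xs = b.sample(rng, 100)
        assert all(b.contains(x) for x in xs)
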