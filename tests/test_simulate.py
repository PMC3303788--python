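import numpy as np
import pytest

from mcmgene import (
    ChainKind,
    PromoterState,
    StepProbabilities,
    ensemble_mean_trace,
    first_stable_cycle,
    simulate_cell,
    simulate_population,
    steady_state_3state_twojump,
    step_expression,
)
from mcmgene.simulate import SimulationConfig, initial_state

LOG10_MEAN_BL = np.exp((0.5 * np.log(10)) ** 2 / 2)  # E[10^z], z~N(0,0.25)

FROZEN_ACT = StepProbabilities.two_state_activator(0.0, 0.0)


class TestStepExpression:
    def test_noise_free_update(self, rng):
        cfg = SimulationConfig().without_noise()
        # X + (alpha*f + BL - gamma*X)*dt with BL = gamma
        assert step_expression(10.0, 1.0, cfg, rng) == pytest.approx(10.2)

    def test_noise_free_fixed_point(self, rng):
        cfg = SimulationConfig().without_noise()
        x_star = (cfg.alpha * 10 + cfg.gamma) / cfg.gamma  # 101
        assert step_expression(x_star, 10.0, cfg, rng) == pytest.approx(101.0)

    def test_mean_update_matches_lognormal_oracle(self, rng):
        cfg = SimulationConfig()
        n = 40_000
        vals = np.array([step_expression(0.0, 1.0, cfg, rng) for _ in range(n)])
        expected = cfg.alpha * 1.0 + cfg.gamma * LOG10_MEAN_BL
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - expected) < 3 * se

    def test_rejects_negative_level(self, rng):
        with pytest.raises(ValueError):
            step_expression(-1.0, 1.0, SimulationConfig(), rng)


class TestSimulateCell:
    def test_frozen_unbound_converges_deterministically(self):
        cfg = SimulationConfig(seed=2).without_noise()
        traj = simulate_cell(ChainKind.ACTIVATOR_ONLY_2STATE, FROZEN_ACT,
                             cfg, cell_seed=0)
        assert np.all(traj.states == PromoterState.UNBOUND)
        limit = (cfg.alpha * 1 + cfg.gamma) / cfg.gamma  # 11
        assert np.all(np.diff(traj.X) >= -1e-12)
        assert traj.X[-1] == pytest.approx(limit, abs=1e-9)

    def test_absorbing_activator_state(self):
        sp = StepProbabilities(p_A1=1.0, p_A2=0.0, p_R1=0.0, p_R2=1.0)
        traj = simulate_cell(ChainKind.COMPETING_3STATE, sp,
                             SimulationConfig(seed=3, t_end=30), cell_seed=1)
        assert traj.states[0] == PromoterState.REPRESSOR_BOUND
        assert np.all(traj.states[1:] == PromoterState.ACTIVATOR_BOUND)

    def test_bit_exact_reproducibility(self):
        sp = StepProbabilities(0.2, 0.3, 0.1, 0.4)
        cfg = SimulationConfig(seed=7, t_end=50)
        a = simulate_cell(ChainKind.COMPETING_3STATE, sp, cfg, cell_seed=5)
        b = simulate_cell(ChainKind.COMPETING_3STATE, sp, cfg, cell_seed=5)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.states, b.states)

    def test_nonnegative_expression(self):
        sp = StepProbabilities(0.2, 0.3, 0.1, 0.4)
        traj = simulate_cell(ChainKind.COMPETING_3STATE, sp,
                             SimulationConfig(seed=11), cell_seed=3)
        assert np.all(traj.X >= 0)


class TestSimulatePopulation:
    def test_deterministic_limit_population(self):
        cfg = SimulationConfig(seed=1, n_cells=200).without_noise()
        pop = simulate_population(ChainKind.ACTIVATOR_ONLY_2STATE, FROZEN_ACT,
                                  0.0, cfg)
        assert pop.sd == pytest.approx(0.0, abs=1e-12)
        assert pop.mean == pytest.approx(11.0, abs=1e-8)

    def test_saturating_activator_mean_field(self):
        cfg = SimulationConfig(seed=4, n_cells=4_000)
        sp = StepProbabilities.two_state_activator(1.0, 0.0)
        pop = simulate_population(ChainKind.ACTIVATOR_ONLY_2STATE, sp, 10.0, cfg)
        expected = (cfg.alpha * 10 + cfg.gamma * LOG10_MEAN_BL) / cfg.gamma
        assert pop.mean == pytest.approx(expected, rel=0.10)

    def test_seeded_determinism(self):
        sp = StepProbabilities(0.2, 0.3, 0.1, 0.4)
        cfg = SimulationConfig(seed=9, n_cells=500, t_end=60)
        a = simulate_population(ChainKind.COMPETING_3STATE, sp, 1.0, cfg)
        b = simulate_population(ChainKind.COMPETING_3STATE, sp, 1.0, cfg)
        assert np.array_equal(a.values, b.values)

    def test_activity_ordering_at_extremes(self):
        """Activator-saturated > unbound-only > repressor-saturated means,
        mirroring the promoter-activity map 10 > 1 > 0."""
        cfg = SimulationConfig(seed=6, n_cells=2_000)
        act = simulate_population(ChainKind.ACTIVATOR_ONLY_2STATE,
                                  StepProbabilities.two_state_activator(0.9, 0.01),
                                  10.0, cfg)
        unb = simulate_population(ChainKind.ACTIVATOR_ONLY_2STATE, FROZEN_ACT,
                                  0.0, cfg)
        rep = simulate_population(ChainKind.REPRESSOR_ONLY_2STATE,
                                  StepProbabilities.two_state_repressor(0.9, 0.01),
                                  0.01, cfg)
        assert act.mean > unb.mean > rep.mean

    def test_empirical_two_jump_occupancy(self):
        sp = StepProbabilities(0.35, 0.3, 0.3, 0.25)
        cfg = SimulationConfig(seed=8, n_cells=3_000)
        pop = simulate_population(ChainKind.COMPETING_3STATE, sp, 1.0, cfg)
        occ = steady_state_3state_twojump(sp)
        # mean expression implied by stationary promoter occupancy
        fbar = occ.pi_U * 1.0 + occ.pi_A * 10.0
        expected = (cfg.alpha * fbar + cfg.gamma * LOG10_MEAN_BL) / cfg.gamma
        assert pop.mean == pytest.approx(expected, rel=0.05)


class TestEnsembleTrace:
    def test_starts_at_zero_and_matches_deterministic_recursion(self):
        cfg = SimulationConfig(seed=2, n_cells=10, t_end=40).without_noise()
        trace = ensemble_mean_trace(ChainKind.ACTIVATOR_ONLY_2STATE,
                                    FROZEN_ACT, 0.0, cfg)
        assert trace["mean_X"].iloc[0] == 0.0
        x, expected = 0.0, []
        for _ in range(cfg.t_end + 1):
            expected.append(x)
            x = x + (cfg.alpha * 1 + cfg.gamma - cfg.gamma * x) * cfg.dt
        assert np.allclose(trace["mean_X"].to_numpy(), expected[: cfg.t_end + 1])

    def test_first_stable_cycle_metric(self):
        trace = np.concatenate([np.linspace(0, 10, 50), np.full(151, 10.0)])
        assert first_stable_cycle(trace) <= 50
        assert first_stable_cycle(np.full(201, 5.0)) == 0


def test_initial_state_is_zero_dox_resting_state():
    assert initial_state(ChainKind.ACTIVATOR_ONLY_2STATE) == PromoterState.UNBOUND
    assert initial_state(ChainKind.REPRESSOR_ONLY_2STATE) == PromoterState.REPRESSOR_BOUND
    assert initial_state(ChainKind.COMPETING_3STATE) == PromoterState.REPRESSOR_BOUND


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(alpha=-1)
    with pytest.raises(ValueError):
        SimulationConfig(update_mode="three_jump")
    with pytest.raises(ValueError):
        SimulationConfig(seed=-1)
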