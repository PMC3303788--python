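import numpy as np
import pytest

import mcmgene as m
from mcmgene import (
    BINDING_PENALTY,
    ChainKind,
    HillParams,
    ObservedCurves,
    SwitchingModel,
    build_observed_curves,
    eval_hill,
    objective_2state,
    objective_3state,
)


@pytest.fixture(scope="module")
def small_grid():
    return m.default_dox_grid(n=12)


class TestObservedCurves:
    def test_reference_values(self, small_grid):
        curves = build_observed_curves(HillParams(0.6, 1.6),
                                       HillParams(0.6, 1.8), small_grid)
        i = int(np.argmin(np.abs(small_grid - 0.6)))
        # activator occupancy is the Hill curve itself
        assert curves.obs_act[i] == pytest.approx(
            eval_hill(HillParams(0.6, 1.6), small_grid[i]))
        # full repression at zero dox; half-repression at K
        assert curves.obs_rep[0] == pytest.approx(1.0)
        assert curves.obs_rep[i] == pytest.approx(
            1.0 - eval_hill(HillParams(0.6, 1.8), small_grid[i]))

    def test_orientation_enforced(self, small_grid):
        act = HillParams(0.6, 1.6)
        with pytest.raises(ValueError, match="non-increasing"):
            ObservedCurves(dox_grid=small_grid,
                           obs_act=np.asarray(eval_hill(act, small_grid)),
                           obs_rep=np.asarray(eval_hill(act, small_grid)),
                           act_params=act, rep_params=act)


def synthetic_three_state():
    """A responsive, binding-contingency-satisfying generating model."""
    return SwitchingModel.three_state(
        HillParams(1.8, 1.7), HillParams(3.5e5, 0.1),
        HillParams(1.0e6, 0.3), HillParams(4.0, 2.2),
    )


def curves_from_model(model, grid):
    occ = model.occupancy_curves(grid[grid > 0])
    return ObservedCurves(
        dox_grid=grid,
        obs_act=np.concatenate([[0.0], occ["P_Act"]]),
        obs_rep=np.concatenate([[1.0], occ["P_Rep"]]),
        act_params=HillParams(0.6, 1.6), rep_params=HillParams(0.6, 1.8),
    )


class TestObjectives:
    def test_perfect_fit_is_zero(self, dox_grid):
        gen = synthetic_three_state()
        curves = curves_from_model(gen, dox_grid)
        assert objective_3state(gen, curves) < 1e-20

    def test_contingency_penalty_dominates(self, dox_grid):
        curves = m.ReferenceCurves().observed_curves(dox_grid)
        # both binding curves near saturation at high dox -> sum >= 1
        bad = SwitchingModel.three_state(
            HillParams(0.05, 2.0), HillParams(1.0, 1.0),
            HillParams(0.05, 2.0), HillParams(1.0, 1.0),
        )
        assert objective_3state(bad, curves) >= BINDING_PENALTY

    def test_matches_naive_loop_oracle(self, dox_grid, rng):
        curves = m.ReferenceCurves().observed_curves(dox_grid)
        for _ in range(5):
            hills = tuple(HillParams(rng.uniform(0.1, 10), rng.uniform(0.3, 3))
                          for _ in range(4))
            model = SwitchingModel(ChainKind.COMPETING_3STATE, hills)
            expected = 0.0
            violated = False
            for dose, oa, orr in zip(curves.dox_grid, curves.obs_act,
                                     curves.obs_rep):
                if dose <= 0:
                    continue
                p = [eval_hill(h, dose) for h in hills]
                expected += (p[0] / (p[0] + p[1]) - oa) ** 2
                expected += (p[2] / (p[2] + p[3]) - orr) ** 2
                if p[0] + p[2] >= 1.0:
                    violated = True
            if violated:
                expected += BINDING_PENALTY
            assert objective_3state(model, curves) == pytest.approx(
                expected, abs=1e-12)

    def test_two_state_naive_oracle(self, dox_grid, rng):
        occ = np.asarray(eval_hill(HillParams(0.6, 1.6), dox_grid))
        for _ in range(5):
            model = SwitchingModel.two_state(
                ChainKind.ACTIVATOR_ONLY_2STATE,
                HillParams(rng.uniform(0.1, 10), rng.uniform(0.3, 3)),
                HillParams(rng.uniform(0.1, 10), rng.uniform(0.3, 3)))
            expected = sum(
                (eval_hill(model.hills[0], dd)
                 / (eval_hill(model.hills[0], dd) + eval_hill(model.hills[1], dd))
                 - oo) ** 2
                for dd, oo in zip(dox_grid, occ) if dd > 0)
            assert objective_2state(model, dox_grid, occ) == pytest.approx(
                expected, abs=1e-12)

    def test_two_state_perfect_fit(self, dox_grid):
        # p2 ~ saturated, p1 = Hill -> occupancy ~ p1/(p1+1)
        model = SwitchingModel.two_state(ChainKind.ACTIVATOR_ONLY_2STATE,
                                         HillParams(0.6, 1.6),
                                         HillParams(0.6, 1.6))
        occ = np.full(dox_grid.size, 0.5)
        assert objective_2state(model, dox_grid, occ) < 1e-20


class TestEstimate:
    def test_three_state_curve_recovery(self, dox_grid):
        """Curves generated by a known constraint-satisfying model are
        recovered to within 0.01 (identifiability caveat: the curve
        surface, not the raw parameters, is the test surface)."""
        gen = synthetic_three_state()
        curves = curves_from_model(gen, dox_grid)
        est = m.estimate(curves, ChainKind.COMPETING_3STATE, seed=11)
        assert est.constraint_satisfied
        assert est.objective_value <= 1e-4
        d = dox_grid[dox_grid > 0]
        rec = est.model.occupancy_curves(d)
        ref = gen.occupancy_curves(d)
        assert np.abs(rec["P_Act"] - ref["P_Act"]).max() <= 0.01
        assert np.abs(rec["P_Rep"] - ref["P_Rep"]).max() <= 0.01

    def test_two_state_reference_fit_quality(self, reference_curves):
        est = m.estimate(reference_curves, ChainKind.ACTIVATOR_ONLY_2STATE,
                         seed=3)
        # amplitude-profiled occupancy misfit within the data resolution
        assert est.objective_value < 0.05
        assert est.constraint_satisfied

    def test_seeded_determinism(self, reference_curves):
        a = m.estimate(reference_curves, ChainKind.REPRESSOR_ONLY_2STATE,
                       seed=19)
        b = m.estimate(reference_curves, ChainKind.REPRESSOR_ONLY_2STATE,
                       seed=19)
        assert a == b

    def test_budget_validation(self, reference_curves):
        with pytest.raises(ValueError):
            m.estimate(reference_curves, ChainKind.ACTIVATOR_ONLY_2STATE,
                       seed=0, budget=10)


class TestSwitchingModelIO:
    def test_frame_round_trip(self):
        gen = synthetic_three_state()
        back = SwitchingModel.from_frame(gen.to_frame(),
                                         ChainKind.COMPETING_3STATE)
        assert back == gen
        assert len(gen.to_frame()) == 8  # 4 Hill functions x (K, H)

    def test_two_state_frame_has_four_rows(self):
        model = SwitchingModel.two_state(ChainKind.ACTIVATOR_ONLY_2STATE,
                                         HillParams(1, 1), HillParams(2, 2))
        assert len(model.to_frame()) == 4

    def test_malformed_frame_names_function(self):
        frame = synthetic_three_state().to_frame()
        frame = frame[frame["function"] != "P_R2"]
        with pytest.raises(ValueError, match="P_R2"):
            SwitchingModel.from_frame(frame, ChainKind.COMPETING_3STATE)
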