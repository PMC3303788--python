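"""Stochastic simulation of single-gene induction.

Each cell carries a promoter-state telegraph (a 2- or 3-state Markov
chain) and an expression level X updated once per time cycle by a noisy
birth-death rule:

    X' = max(0, X + (alpha * f + BL - gamma * delta * X) * dt)

where f is the promoter activity of the current state (0 for
repressor-bound, 1 for unbound, 10 for activator-bound by default),
delta ~ N(1, 0.5^2) perturbs the degradation rate, and BL = gamma * 10^z
with z ~ N(0, 0.5^2) is the basal (leaky) expression term that models the
background signal seen by FACS at zero induction.  The promoter state is
updated first within a cycle; the expression update uses the post-update
state.  X is clamped at zero because the degradation-noise factor delta
is occasionally negative.

Populations are ensembles of independent cells.  For speed the
population simulator advances all cells in lock-step with batched random
draws from a single generator seeded deterministically from
(config seed, dose); results are bit-reproducible for a fixed
(seed, dose, n_cells).  The scalar single-cell API uses a per-cell child
seed instead, so an individual trajectory is reproducible from
(seed, cell index) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chain import (
    ChainKind,
    PromoterState,
    StepProbabilities,
    step_3state,
)
from .estimation import SwitchingModel

__all__ = [
    "SimulationConfig",
    "initial_state",
    "Trajectory",
    "PopulationSample",
    "step_expression",
    "simulate_cell",
    "simulate_population",
    "ensemble_mean_trace",
    "occupancy_fractions",
    "first_stable_cycle",
]

DEFAULT_ACTIVITY = {
    PromoterState.REPRESSOR_BOUND: 0.0,
    PromoterState.UNBOUND: 1.0,
    PromoterState.ACTIVATOR_BOUND: 10.0,
}


def initial_state(chain: ChainKind) -> PromoterState:
    """Promoter state at induction onset: the zero-dox resting state.

    Cells are grown without inducer before the experiment starts, so a
    chain that contains the repressor begins repressor-bound (without dox
    the repressor occupies the site), while the activator-only chain
    begins unbound (the activator is inactive without dox).
    """
    if chain == ChainKind.ACTIVATOR_ONLY_2STATE:
        return PromoterState.UNBOUND
    return PromoterState.REPRESSOR_BOUND


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the birth-death expression solver.

    Defaults are the reference conditions: transcription rate alpha = 2.0
    (arbitrary units per cycle), degradation rate gamma = 0.2 per cycle,
    dt = 1 cycle, 200 cycles, 10,000 cells, both noise SDs 0.5, promoter
    activity {repressor-bound: 0, unbound: 1, activator-bound: 10}, and
    two-jump promoter updates for the 3-state chain.
    """

    alpha: float = 2.0
    gamma: float = 0.2
    dt: float = 1.0
    t_end: int = 200
    n_cells: int = 10_000
    deg_noise_sd: float = 0.5
    bl_noise_sd: float = 0.5
    activity_map: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITY))
    update_mode: str = "two_jump"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0 or self.dt <= 0:
            raise ValueError("alpha, gamma and dt must be > 0")
        if self.t_end < 1 or self.n_cells < 1:
            raise ValueError("t_end and n_cells must be >= 1")
        if self.deg_noise_sd < 0 or self.bl_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.update_mode not in ("two_jump", "single_jump"):
            raise ValueError("update_mode must be 'two_jump' or 'single_jump'")
        if any(v < 0 for v in self.activity_map.values()):
            raise ValueError("promoter activities must be nonnegative")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    def without_noise(self) -> "SimulationConfig":
        """Copy with both noise SDs zero (delta = 1, BL = gamma exactly)."""
        return replace(self, deg_noise_sd=0.0, bl_noise_sd=0.0)

    @property
    def two_jump(self) -> bool:
        return self.update_mode == "two_jump"

    def activity_vector(self) -> np.ndarray:
        """Activity indexed by PromoterState integer value (R, U, A)."""
        return np.array([self.activity_map[PromoterState(i)] for i in range(3)],
                        dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A single cell's telegraph and expression time series."""

    times: np.ndarray
    X: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.X) == len(self.states)):
            raise ValueError("times, X and states must have equal length")
        if np.any(self.X < 0):
            raise ValueError("expression levels must be nonnegative")


@dataclass(frozen=True)
class PopulationSample:
    """Steady-state expression of a cell population at one dose."""

    dox: float
    values: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_values(cls, dox: float, values: np.ndarray) -> "PopulationSample":
        v = np.asarray(values, dtype=float)
        return cls(dox=float(dox), values=v, mean=float(np.mean(v)),
                   sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0)


def step_expression(X: float, f: float, cfg: SimulationConfig,
                    rng: np.random.Generator) -> float:
    """One birth-death update of the expression level.

    Consumes exactly two normal draws: delta ~ N(1, deg_noise_sd^2) on the
    degradation term, then z ~ N(0, bl_noise_sd^2) for the basal level
    BL = gamma * 10^z.
    """
    if X < 0:
        raise ValueError("X must be nonnegative")
    delta = rng.normal(1.0, cfg.deg_noise_sd)
    z = rng.normal(0.0, cfg.bl_noise_sd)
    bl = cfg.gamma * 10.0**z
    return max(0.0, X + (cfg.alpha * f + bl - cfg.gamma * delta * X) * cfg.dt)


def _cell_rng(cfg: SimulationConfig, cell_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, int(cell_seed)]))


def simulate_cell(chain: ChainKind, sp: StepProbabilities,
                  cfg: SimulationConfig, cell_seed: int) -> Trajectory:
    """Simulate one cell: alternate a promoter-state update and an
    expression update per cycle, starting from X = 0 in the chain's
    zero-dox resting state (see :func:`initial_state`).

    Reproducible bit-exactly from (cfg.seed, cell_seed).
    """
    rng = _cell_rng(cfg, cell_seed)
    two_jump = cfg.two_jump and chain == ChainKind.COMPETING_3STATE
    act = cfg.activity_vector()
    n = cfg.t_end
    states = np.empty(n + 1, dtype=np.int64)
    X = np.empty(n + 1, dtype=float)
    state = initial_state(chain)
    x = 0.0
    states[0], X[0] = state, x
    for t in range(1, n + 1):
        state = step_3state(state, sp, rng, two_jump=two_jump)
        x = step_expression(x, act[state], cfg, rng)
        states[t], X[t] = state, x
    return Trajectory(times=np.arange(n + 1), X=X, states=states)


def _dose_entropy(dox: float) -> int:
    # stable 64-bit key from the dose's IEEE-754 bits
    return int(np.float64(dox).view(np.uint64))


def _population_rng(cfg: SimulationConfig, dox: float) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _dose_entropy(dox)])
    )


def _step_states_batch(states: np.ndarray, sp: StepProbabilities,
                       rng: np.random.Generator, two_jump: bool) -> np.ndarray:
    """Vectorized per-step update of all cells' promoter states."""
    n = states.size
    u1 = rng.random(n)
    u2 = rng.random(n)
    new = states.copy()
    is_u = states == PromoterState.UNBOUND
    is_a = states == PromoterState.ACTIVATOR_BOUND
    is_r = states == PromoterState.REPRESSOR_BOUND
    # unbound: one partitioned draw (valid because p_A1 + p_R1 <= 1)
    new[is_u & (u1 < sp.p_A1)] = PromoterState.ACTIVATOR_BOUND
    new[is_u & (u1 >= sp.p_A1) & (u1 < sp.p_A1 + sp.p_R1)] = PromoterState.REPRESSOR_BOUND
    leave_a = is_a & (u1 < sp.p_A2)
    leave_r = is_r & (u1 < sp.p_R2)
    left = leave_a | leave_r
    new[left] = PromoterState.UNBOUND
    if two_jump:
        # unbinding cells pass through UNBOUND and resolve within the step
        new[left & (u2 < sp.p_A1)] = PromoterState.ACTIVATOR_BOUND
        new[left & (u2 >= sp.p_A1) & (u2 < sp.p_A1 + sp.p_R1)] = PromoterState.REPRESSOR_BOUND
    return new


def _resolve_sp(model, chain: ChainKind, dox: float) -> StepProbabilities:
    if isinstance(model, StepProbabilities):
        return model
    if isinstance(model, SwitchingModel):
        if model.chain != chain:
            raise ValueError(f"model is for {model.chain.value}, not {chain.value}")
        return model.step_probabilities(dox)
    raise TypeError("model must be a SwitchingModel or StepProbabilities")


def _run_batch(chain: ChainKind, sp: StepProbabilities, cfg: SimulationConfig,
               rng: np.random.Generator, record_trace: bool = False,
               state_burn_in: int | None = None):
    two_jump = cfg.two_jump and chain == ChainKind.COMPETING_3STATE
    act = cfg.activity_vector()
    n = cfg.n_cells
    states = np.full(n, int(initial_state(chain)), dtype=np.int64)
    X = np.zeros(n)
    means = np.zeros(cfg.t_end + 1) if record_trace else None
    sds = np.zeros(cfg.t_end + 1) if record_trace else None
    counts = np.zeros(3, dtype=np.int64)
    for t in range(1, cfg.t_end + 1):
        states = _step_states_batch(states, sp, rng, two_jump)
        delta = rng.normal(1.0, cfg.deg_noise_sd, n)
        z = rng.normal(0.0, cfg.bl_noise_sd, n)
        X = np.maximum(
            0.0,
            X + (cfg.alpha * act[states] + cfg.gamma * 10.0**z
                 - cfg.gamma * delta * X) * cfg.dt,
        )
        if record_trace:
            means[t] = X.mean()
            sds[t] = X.std(ddof=1) if n > 1 else 0.0
        if state_burn_in is not None and t >= state_burn_in:
            counts += np.bincount(states, minlength=3)
    return X, means, sds, counts


def simulate_population(chain: ChainKind, model, dox: float,
                        cfg: SimulationConfig) -> PopulationSample:
    """Steady-state expression of ``cfg.n_cells`` independent cells.

    ``model`` may be a SwitchingModel (evaluated at ``dox``) or a raw
    StepProbabilities.  X is recorded at the final cycle.
    """
    sp = _resolve_sp(model, chain, dox)
    rng = _population_rng(cfg, dox)
    X, _, _, _ = _run_batch(chain, sp, cfg, rng)
    return PopulationSample.from_values(dox, X)


def ensemble_mean_trace(chain: ChainKind, model, dox: float,
                        cfg: SimulationConfig) -> pd.DataFrame:
    """Per-cycle ensemble mean (and SD) of X over the population."""
    sp = _resolve_sp(model, chain, dox)
    rng = _population_rng(cfg, dox)
    _, means, sds, _ = _run_batch(chain, sp, cfg, rng, record_trace=True)
    return pd.DataFrame({"cycle": np.arange(cfg.t_end + 1),
                         "mean_X": means, "sd_X": sds})


def occupancy_fractions(chain: ChainKind, model, dox: float,
                        cfg: SimulationConfig, burn_in: int = 100) -> np.ndarray:
    """Promoter-state fractions (R, U, A) pooled over cells and cycles
    ``burn_in``..t_end; an empirical check of the stationary law."""
    sp = _resolve_sp(model, chain, dox)
    rng = _population_rng(cfg, dox)
    _, _, _, counts = _run_batch(chain, sp, cfg, rng, state_burn_in=burn_in)
    return counts / counts.sum()


def first_stable_cycle(mean_trace: np.ndarray, rel_tol: float = 0.05) -> int:
    """First cycle after which the ensemble mean stays within ``rel_tol``
    of its final value; the convergence-onset summary of a mean trace."""
    m = np.asarray(mean_trace, dtype=float)
    final = m[-1]
    if final == 0:
        return 0
    outside = np.abs(m - final) > rel_tol * abs(final)
    if not outside.any():
        return 0
    return int(np.nonzero(outside)[0][-1]) + 1
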