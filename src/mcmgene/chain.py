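"""Discrete-time promoter-state Markov chains.

The promoter of the reporter gene is modeled as a Markov chain over up to
three states: repressor-bound, unbound (neither factor bound) and
activator-bound.  Activator and repressor compete for the same regulatory
region and cannot be bound simultaneously ("binding contingency"), so the
3-state chain has no direct repressor-bound <-> activator-bound jump and
the two exit probabilities from the unbound state must satisfy
p_A1 + p_R1 <= 1.

Two per-step semantics are supported for the 3-state chain:

* ``single_jump`` — at most one transition per time step; its stationary
  law has the closed form pi_A : pi_U : pi_R = p_A1/p_A2 : 1 : p_R1/p_R2.
* ``two_jump`` — a bound state that unbinds within a step immediately
  performs, in the same step, a full unbound-state update (it may re-bind
  the same factor, bind the competing factor, or remain unbound).  The
  unbound state is a waypoint that is passed through rather than dwelt
  in, which prevents its over-occupancy; this is the default simulation
  mode.  Direct repressor<->activator switching still never happens in a
  single jump.

Switching happens iff the uniform draw r satisfies r < p (strict), so
p = 0 means never and p = 1 means always.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "ChainKind",
    "PromoterState",
    "StepProbabilities",
    "StateOccupancy",
    "TwoStateOccupancy",
    "DegenerateChainError",
    "steady_state_2state",
    "steady_state_3state_singlejump",
    "steady_state_3state_twojump",
    "transition_matrix_3state",
    "step_2state",
    "step_3state",
]


class ChainKind(str, Enum):
    ACTIVATOR_ONLY_2STATE = "activator_only_2state"
    REPRESSOR_ONLY_2STATE = "repressor_only_2state"
    COMPETING_3STATE = "competing_3state"


class PromoterState(IntEnum):
    REPRESSOR_BOUND = 0
    UNBOUND = 1
    ACTIVATOR_BOUND = 2


class DegenerateChainError(RuntimeError):
    """Chain has no unique stationary distribution."""


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name}={p!r} is not a probability in [0, 1]")


@dataclass(frozen=True)
class StepProbabilities:
    """Per-step switching probabilities of the 3-state chain.

    p_A1: UNBOUND -> ACTIVATOR_BOUND, p_A2: ACTIVATOR_BOUND -> UNBOUND,
    p_R1: UNBOUND -> REPRESSOR_BOUND, p_R2: REPRESSOR_BOUND -> UNBOUND.

    2-state chains are embedded by zeroing the unused binding probability
    (see :meth:`two_state_activator` / :meth:`two_state_repressor`), which
    makes the opposite bound state unreachable.
    """

    p_A1: float
    p_A2: float
    p_R1: float
    p_R2: float

    def __post_init__(self) -> None:
        for name in ("p_A1", "p_A2", "p_R1", "p_R2"):
            _check_prob(name, getattr(self, name))
        if self.p_A1 + self.p_R1 > 1.0 + 1e-12:
            raise ValueError(
                "binding contingency violated: p_A1 + p_R1 = "
                f"{self.p_A1 + self.p_R1:.6g} > 1"
            )

    @classmethod
    def two_state_activator(cls, p1: float, p2: float) -> "StepProbabilities":
        """Activator-only chain: UNBOUND (OFF) <-> ACTIVATOR_BOUND (ON)."""
        return cls(p_A1=p1, p_A2=p2, p_R1=0.0, p_R2=1.0)

    @classmethod
    def two_state_repressor(cls, p1: float, p2: float) -> "StepProbabilities":
        """Repressor-only chain: UNBOUND <-> REPRESSOR_BOUND (p1 binds)."""
        return cls(p_A1=0.0, p_A2=1.0, p_R1=p1, p_R2=p2)


@dataclass(frozen=True)
class TwoStateOccupancy:
    """Stationary law of a 2-state (OFF/ON) chain."""

    p_on: float
    p_off: float

    def __post_init__(self) -> None:
        if abs(self.p_on + self.p_off - 1.0) > 1e-12:
            raise ValueError("occupancies must sum to 1")


@dataclass(frozen=True)
class StateOccupancy:
    """Stationary law over (repressor-bound, unbound, activator-bound)."""

    pi_R: float
    pi_U: float
    pi_A: float

    def __post_init__(self) -> None:
        for name in ("pi_R", "pi_U", "pi_A"):
            _check_prob(name, getattr(self, name))
        if abs(self.pi_R + self.pi_U + self.pi_A - 1.0) > 1e-12:
            raise ValueError("occupancies must sum to 1 within 1e-12")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_R, self.pi_U, self.pi_A])


def steady_state_2state(p1: float, p2: float) -> TwoStateOccupancy:
    """Stationary distribution of the OFF <-> ON telegraph chain.

    P_ON = p1 / (p1 + p2), P_OFF = p2 / (p1 + p2).
    """
    _check_prob("p1", p1)
    _check_prob("p2", p2)
    if p1 + p2 <= 0.0:
        raise DegenerateChainError(
            "p1 = p2 = 0: frozen chain has no unique stationary distribution"
        )
    p_on = p1 / (p1 + p2)
    return TwoStateOccupancy(p_on=p_on, p_off=1.0 - p_on)


def steady_state_3state_singlejump(sp: StepProbabilities) -> StateOccupancy:
    """Closed-form stationary law under single-jump semantics.

    Detailed balance across each edge gives
    pi_A = (p_A1/p_A2)/Z, pi_R = (p_R1/p_R2)/Z, pi_U = 1/Z
    with Z = 1 + p_A1/p_A2 + p_R1/p_R2.
    """
    if sp.p_A2 <= 0.0 or sp.p_R2 <= 0.0:
        raise DegenerateChainError(
            "p_A2 and p_R2 must be > 0 for a unique stationary distribution"
        )
    ra = sp.p_A1 / sp.p_A2
    rr = sp.p_R1 / sp.p_R2
    z = 1.0 + ra + rr
    return StateOccupancy(pi_R=rr / z, pi_U=1.0 / z, pi_A=ra / z)


def transition_matrix_3state(sp: StepProbabilities, two_jump: bool) -> np.ndarray:
    """One-step transition matrix, rows = from-state (R, U, A).

    Under two-jump semantics a bound state that unbinds performs a full
    unbound-state update within the same step (re-bind the same factor,
    bind the competing one, or stay unbound); exits from UNBOUND always
    use a single partitioned draw.
    """
    a1, a2, r1, r2 = sp.p_A1, sp.p_A2, sp.p_R1, sp.p_R2
    m = np.zeros((3, 3))
    u = PromoterState.UNBOUND
    r = PromoterState.REPRESSOR_BOUND
    a = PromoterState.ACTIVATOR_BOUND
    m[u, a] = a1
    m[u, r] = r1
    m[u, u] = 1.0 - a1 - r1
    if two_jump:
        m[a, r] = a2 * r1
        m[a, u] = a2 * (1.0 - a1 - r1)
        m[a, a] = 1.0 - a2 + a2 * a1
        m[r, a] = r2 * a1
        m[r, u] = r2 * (1.0 - a1 - r1)
        m[r, r] = 1.0 - r2 + r2 * r1
    else:
        m[a, u] = a2
        m[a, a] = 1.0 - a2
        m[r, u] = r2
        m[r, r] = 1.0 - r2
    return m


def _power_iteration(m: np.ndarray, tol: float = 1e-14, max_iter: int = 200_000) -> np.ndarray:
    """Stationary row vector of a stochastic matrix by power iteration.

    Raises DegenerateChainError if the stationary law is not unique
    (different starting points converge to different limits).
    """
    # lazy kernel (M + M^2)/2 shares M's stationary laws and is aperiodic
    lazy = 0.5 * (m + m @ m)
    limits = []
    for start in range(m.shape[0]):
        v = np.zeros(m.shape[0])
        v[start] = 1.0
        for _ in range(max_iter):
            nxt = v @ lazy
            nxt = nxt / nxt.sum()
            if np.max(np.abs(nxt - v)) < tol:
                v = nxt
                break
            v = nxt
        limits.append(v)
    ref = limits[0]
    for v in limits[1:]:
        if np.max(np.abs(v - ref)) > 1e-9:
            raise DegenerateChainError(
                "reducible chain: stationary distribution is not unique"
            )
    return ref


def steady_state_3state_twojump(sp: StepProbabilities) -> StateOccupancy:
    """Stationary law of the composite (two-jump) per-step kernel.

    Computed by power iteration of the explicit 3x3 composite matrix to
    below 1e-12; raises if the composite chain is reducible.
    """
    m = transition_matrix_3state(sp, two_jump=True)
    pi = _power_iteration(m)
    pi = np.clip(pi, 0.0, 1.0)
    pi = pi / pi.sum()
    return StateOccupancy(pi_R=float(pi[0]), pi_U=float(pi[1]), pi_A=float(pi[2]))


def step_2state(state: PromoterState, p1: float, p2: float, r: float) -> PromoterState:
    """One update of a 2-state chain between UNBOUND (OFF) and a bound state.

    ``state`` must be UNBOUND or a bound state; from UNBOUND the chain
    binds iff r < p1, from the bound state it unbinds iff r < p2.  Which
    bound state is in play is implied by ``state`` (UNBOUND inputs return
    ACTIVATOR_BOUND; use :func:`step_3state` with an embedded 2-state
    StepProbabilities when the repressor chain must bind from UNBOUND).
    """
    _check_prob("p1", p1)
    _check_prob("p2", p2)
    if state == PromoterState.UNBOUND:
        return PromoterState.ACTIVATOR_BOUND if r < p1 else PromoterState.UNBOUND
    return PromoterState.UNBOUND if r < p2 else state


def step_3state(
    state: PromoterState,
    sp: StepProbabilities,
    rng: np.random.Generator,
    two_jump: bool = True,
) -> PromoterState:
    """One per-step update of the 3-state chain.

    From UNBOUND a single partitioned uniform draw selects the successor
    (r < p_A1 -> activator-bound, p_A1 <= r < p_A1+p_R1 -> repressor-bound,
    else stay); the partition is well defined because binding contingency
    guarantees p_A1 + p_R1 <= 1.  Under two-jump semantics a bound state
    that unbinds performs, within the same step, a full unbound-state
    update with a second draw (it may re-bind the same factor, bind the
    competing one, or stay unbound).
    """

    def resolve_unbound(r: float) -> PromoterState:
        if r < sp.p_A1:
            return PromoterState.ACTIVATOR_BOUND
        if r < sp.p_A1 + sp.p_R1:
            return PromoterState.REPRESSOR_BOUND
        return PromoterState.UNBOUND

    if state == PromoterState.UNBOUND:
        return resolve_unbound(rng.random())
    if state == PromoterState.ACTIVATOR_BOUND:
        if rng.random() < sp.p_A2:
            if two_jump:
                return resolve_unbound(rng.random())
            return PromoterState.UNBOUND
        return PromoterState.ACTIVATOR_BOUND
    # REPRESSOR_BOUND
    if rng.random() < sp.p_R2:
        if two_jump:
            return resolve_unbound(rng.random())
        return PromoterState.UNBOUND
    return PromoterState.REPRESSOR_BOUND
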