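"""Simulated dose-response curves and Hill-coefficient prediction.

The headline computation: simulate the population's steady-state mean
expression over a dose grid for the activator-only, repressor-only and
combined (activator+repressor) chains, min-max normalize the means, fit a
Hill function to each normalized curve, and compare the fitted Hill
coefficient of the combined system with the customary add/multiply
combinations of the single-factor coefficients.

The key qualitative prediction is that competition for a shared binding
site (binding contingency) makes the combined dose-response curve steeper
than either single-factor curve, and quantitatively close to the observed
Hill coefficient 3.2 rather than the customary 1.6 + 1.8 = 3.4 or
1.6 x 1.8 = 2.88.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .chain import ChainKind
from .estimation import (
    ObservedCurves,
    SwitchingModel,
    build_observed_curves,
    default_dox_grid,
    estimate,
)
from .hill import HillFit, HillParams, fit_hill
from .simulate import SimulationConfig, simulate_population

__all__ = [
    "DoseResponseTable",
    "PredictionReport",
    "ReferenceCurves",
    "run_dose_response",
    "predict_hill",
    "combine_hill",
    "mode_count",
    "run_prediction",
]


@dataclass(frozen=True)
class DoseResponseTable:
    """Simulated dose-response rows: (dox, mean_X, sd_X, norm_mean).

    ``norm_mean`` is the min-max normalization of ``mean_X`` across the
    grid, so it attains exactly 0 and 1 at the extreme means.
    """

    frame: pd.DataFrame
    chain: ChainKind

    def __post_init__(self) -> None:
        need = {"dox", "mean_X", "sd_X", "norm_mean"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"table must have columns {sorted(need)}")
        d = self.frame["dox"].to_numpy()
        if np.any(np.diff(d) < 0):
            raise ValueError("rows must be sorted by dox ascending")
        nm = self.frame["norm_mean"].to_numpy()
        if not (np.isclose(nm.min(), 0.0) and np.isclose(nm.max(), 1.0)):
            raise ValueError("norm_mean must attain 0 and 1 (min-max)")

    @property
    def n_doses(self) -> int:
        return len(self.frame)


def _min_max(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise ValueError("cannot normalize a flat dose-response curve")
    return (values - lo) / (hi - lo)


def run_dose_response(chain: ChainKind, model: SwitchingModel, dox_grid,
                      cfg: SimulationConfig) -> DoseResponseTable:
    """One population simulation per dose; min-max normalized means."""
    d = np.sort(np.asarray(dox_grid, dtype=float))
    if d.size < 7:
        raise ValueError("dose grid needs >= 7 doses")
    means = np.empty(d.size)
    sds = np.empty(d.size)
    for i, dox in enumerate(d):
        samp = simulate_population(chain, model, float(dox), cfg)
        means[i], sds[i] = samp.mean, samp.sd
    frame = pd.DataFrame({
        "dox": d,
        "mean_X": means,
        "sd_X": sds,
        "norm_mean": _min_max(means),
    })
    return DoseResponseTable(frame=frame, chain=chain)


def predict_hill(table: DoseResponseTable) -> HillFit:
    """Hill fit of the normalized dose-response means."""
    if table.n_doses < 7:
        raise ValueError("need >= 7 doses to deduce a Hill function")
    return fit_hill(table.frame["dox"].to_numpy(),
                    table.frame["norm_mean"].to_numpy())


def combine_hill(h_act: float, h_rep: float, mode: str) -> float:
    """Customary combination of single-factor Hill coefficients."""
    if h_act <= 0 or h_rep <= 0:
        raise ValueError("Hill coefficients must be positive")
    if mode == "add":
        return h_act + h_rep
    if mode == "multiply":
        return h_act * h_rep
    raise ValueError(f"unknown mode {mode!r}: use 'add' or 'multiply'")


def mode_count(values, floor: float = 0.01, rel_height: float = 0.05,
               grid_size: int = 512) -> int:
    """Number of modes of the log-scale expression distribution.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on
    log10(X + floor); local maxima below ``rel_height`` of the global
    peak are ignored.  Distinguishes all-or-none (2 modes) from graded
    (1 mode) population responses.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 100:
        raise ValueError("need >= 100 values to count modes")
    logv = np.log10(v + floor)
    if np.ptp(logv) < 1e-9:
        return 1
    kde = gaussian_kde(logv, bw_method="silverman")
    pad = 3.0 * kde.factor * logv.std(ddof=1)
    grid = np.linspace(logv.min() - pad, logv.max() + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = dens[1:-1][interior]
    return int(np.sum(peaks >= rel_height * dens.max()))


@dataclass(frozen=True)
class ReferenceCurves:
    """Reference Hill parameters of the observed single-factor curves."""

    H_act: float = 1.6
    K_act: float = 0.6
    H_rep: float = 1.8
    K_rep: float = 0.6

    @property
    def act_params(self) -> HillParams:
        return HillParams(self.K_act, self.H_act)

    @property
    def rep_params(self) -> HillParams:
        return HillParams(self.K_rep, self.H_rep)

    def observed_curves(self, dox_grid) -> ObservedCurves:
        return build_observed_curves(self.act_params, self.rep_params, dox_grid)


@dataclass(frozen=True)
class PredictionReport:
    """Fitted Hill coefficients of the three chains plus the customary
    add/multiply combinations and the observed reference values."""

    fit_act: HillFit
    fit_rep: HillFit
    fit_combined: HillFit
    calc_add: float
    calc_mult: float
    observed_reference: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "H_activator_only", "value": self.fit_act.params.H,
             "se": self.fit_act.se_H},
            {"quantity": "H_repressor_only", "value": self.fit_rep.params.H,
             "se": self.fit_rep.se_H},
            {"quantity": "H_combined", "value": self.fit_combined.params.H,
             "se": self.fit_combined.se_H},
            {"quantity": "K_combined", "value": self.fit_combined.params.K,
             "se": self.fit_combined.se_K},
            {"quantity": "calc_add", "value": self.calc_add, "se": np.nan},
            {"quantity": "calc_mult", "value": self.calc_mult, "se": np.nan},
            {"quantity": "observed_act", "value": self.observed_reference["act"],
             "se": np.nan},
            {"quantity": "observed_rep", "value": self.observed_reference["rep"],
             "se": np.nan},
            {"quantity": "observed_combined",
             "value": self.observed_reference["combined"], "se": np.nan},
        ]
        return pd.DataFrame(rows)


_CHAIN_SEED_OFFSET = {
    ChainKind.ACTIVATOR_ONLY_2STATE: 1,
    ChainKind.REPRESSOR_ONLY_2STATE: 2,
    ChainKind.COMPETING_3STATE: 3,
}


def chain_seed(seed: int, chain: ChainKind) -> int:
    """Deterministic per-chain optimizer seed below 2**31."""
    words = np.random.SeedSequence([seed, _CHAIN_SEED_OFFSET[chain]])
    return int(words.generate_state(1)[0] & 0x7FFFFFFF)


def run_prediction(reference: ReferenceCurves | None = None,
                   cfg: SimulationConfig | None = None,
                   dox_grid=None, seed: int = 0, budget: int = 50_000,
                   ) -> tuple[PredictionReport, dict]:
    """End-to-end pipeline: estimate -> simulate -> fit for all chains.

    Returns the PredictionReport and a dict of artifacts per chain:
    {"estimation": EstimationResult, "table": DoseResponseTable}.
    """
    reference = reference or ReferenceCurves()
    cfg = cfg or SimulationConfig(seed=seed)
    grid = default_dox_grid() if dox_grid is None else np.asarray(dox_grid, float)
    curves = reference.observed_curves(grid)

    artifacts: dict = {}
    fits: dict = {}
    for chain in (ChainKind.ACTIVATOR_ONLY_2STATE,
                  ChainKind.REPRESSOR_ONLY_2STATE,
                  ChainKind.COMPETING_3STATE):
        est = estimate(curves, chain, seed=chain_seed(seed, chain), budget=budget)
        table = run_dose_response(chain, est.model, grid, cfg)
        fits[chain] = predict_hill(table)
        artifacts[chain] = {"estimation": est, "table": table}

    report = PredictionReport(
        fit_act=fits[ChainKind.ACTIVATOR_ONLY_2STATE],
        fit_rep=fits[ChainKind.REPRESSOR_ONLY_2STATE],
        fit_combined=fits[ChainKind.COMPETING_3STATE],
        calc_add=combine_hill(reference.H_act, reference.H_rep, "add"),
        calc_mult=combine_hill(reference.H_act, reference.H_rep, "multiply"),
        observed_reference={"act": reference.H_act, "rep": reference.H_rep,
                            "combined": 3.2},
    )
    return report, artifacts
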