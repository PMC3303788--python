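"""Hill-function gene-regulatory functions (GRFs).

A GRF maps an inducer concentration to a promoter-state switching
probability or a normalized expression level.  Throughout the package the
GRF is the two-parameter Hill function

    h(x) = x**H / (K**H + x**H)

with effective concentration ``K`` (the half-maximal input, µg/ml) and Hill
coefficient ``H`` (steepness / apparent cooperativity).  The curve has
fixed asymptotes 0 and 1, matching its probabilistic interpretation;
decreasing responses are represented upstream as ``1 - h(x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["HillParams", "HillFit", "HillFitError", "eval_hill", "fit_hill"]

# Bounded search box for (K, H); generous relative to the µg/ml dose scale.
K_BOUNDS = (1e-3, 1e3)
H_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class HillParams:
    """Parameters of a saturating Hill curve.

    Attributes
    ----------
    K : float
        Effective concentration (half-maximal input), strictly positive.
    H : float
        Hill coefficient, strictly positive.
    """

    K: float
    H: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError(f"K must be finite and > 0, got {self.K!r}")
        if not (np.isfinite(self.H) and self.H > 0):
            raise ValueError(f"H must be finite and > 0, got {self.H!r}")

    def __call__(self, x):
        return eval_hill(self, x)


@dataclass(frozen=True)
class HillFit:
    """A least-squares Hill fit with curvature-based standard errors."""

    params: HillParams
    se_K: float
    se_H: float
    residual_sum_of_squares: float
    n_points: int

    def __post_init__(self) -> None:
        if self.se_K < 0 or self.se_H < 0:
            raise ValueError("standard errors must be nonnegative")
        if self.residual_sum_of_squares < 0:
            raise ValueError("residual sum of squares must be nonnegative")


class HillFitError(RuntimeError):
    """Raised when dose-response data cannot support a Hill fit."""


def eval_hill(params: HillParams, x):
    """Evaluate the Hill curve at nonnegative concentration(s) ``x``.

    Returns a float for scalar input, an ndarray for array input.  The
    value is 0 at ``x = 0``, 0.5 at ``x = K`` and tends to 1 as x grows.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("concentrations must be finite and >= 0")
    # Evaluate on the ratio (x/K)**H for numerical range safety.
    with np.errstate(divide="ignore"):
        ratio = np.power(arr / params.K, params.H)
    out = ratio / (1.0 + ratio)
    out = np.where(arr == 0.0, 0.0, out)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def fit_hill(doses, responses) -> HillFit:
    """Fit a two-parameter Hill curve by nonlinear least squares.

    Parameters
    ----------
    doses : array-like
        Nonnegative concentrations, at least 4 points, at least one > 0.
    responses : array-like
        Normalized responses in [0, 1], same length as ``doses``.

    Returns
    -------
    HillFit
        Estimates with standard errors from the local curvature of the
        residual surface (Gauss-Newton approximation of the Hessian).

    Notes
    -----
    The start point is K = geometric mean of the positive doses, H = 1,
    and the search is bounded to K in [1e-3, 1e3], H in [0.1, 10]; the fit
    is deterministic given the data.  Zero-dose points participate with a
    model value of exactly 0.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be 1-D and equal length")
    if d.size < 4:
        raise HillFitError("need at least 4 dose-response points")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    if not np.any(d > 0):
        raise HillFitError("need at least one positive dose")
    if np.any(y < -1e-9) or np.any(y > 1 + 1e-9):
        raise ValueError("responses must be normalized to [0, 1]")
    if np.ptp(y) < 1e-12:
        raise HillFitError(
            "degenerate data: all responses equal; a Hill curve cannot be "
            "identified from a flat response"
        )

    k0 = float(np.exp(np.mean(np.log(d[d > 0]))))
    k0 = min(max(k0, K_BOUNDS[0]), K_BOUNDS[1])
    x0 = np.array([k0, 1.0])

    def resid(theta):
        return eval_hill(HillParams(theta[0], theta[1]), d) - y

    sol = least_squares(
        resid,
        x0,
        bounds=([K_BOUNDS[0], H_BOUNDS[0]], [K_BOUNDS[1], H_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise HillFitError(f"Hill fit failed to converge: {sol.message}")

    rss = float(np.sum(sol.fun**2))
    n = d.size
    dof = max(n - 2, 1)
    s2 = rss / dof
    # covariance from the Gauss-Newton curvature at the optimum
    jtj = sol.jac.T @ sol.jac
    cov = s2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return HillFit(
        params=HillParams(float(sol.x[0]), float(sol.x[1])),
        se_K=float(se[0]),
        se_H=float(se[1]),
        residual_sum_of_squares=rss,
        n_points=int(n),
    )
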