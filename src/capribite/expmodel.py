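"""Exponential cumulative-intake model: y(t) = a * (1 - exp(-b t)).

``a`` is the asymptotic intake (g DM/kg BW), ``b`` the fractional rate of
intake (per min), and the product ``a*b`` the initial rate of intake.  The
model describes a single decelerating meal well; its residual error (RMSE)
grows when intake is split over several bouts, which makes the RMSE itself
an informative trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import IntakeProfile


@dataclass
class ExpFit:
    a: float  # asymptote, g DM/kg BW
    b: float  # fractional rate of intake, per min
    rmse: float  # g DM/kg BW, sqrt(SSE / n)
    n_points: int
    converged: bool

    @property
    def ab(self) -> float:
        """Initial rate of intake, g DM/kg BW per min."""
        return self.a * self.b


def predict_exponential(fit: ExpFit, t) -> np.ndarray | float:
    """Model prediction a*(1 - exp(-b t)); 0 at t=0, asymptote a for large t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = fit.a * (-np.expm1(-fit.b * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def model_rmse(a: float, b: float, profile: IntakeProfile) -> float:
    """Root mean squared residual over all profile points (no df correction)."""
    resid = profile.y - a * (-np.expm1(-b * profile.t))
    return float(np.sqrt(np.mean(resid**2)))


def _moment_b0(t: np.ndarray, y: np.ndarray, a0: float) -> float:
    # time at which the curve reaches half its final value -> b = ln2 / t_half
    if a0 <= 0:
        return 1e-3
    idx = np.searchsorted(y, 0.5 * a0)
    t_half = t[min(idx, len(t) - 1)]
    return float(np.log(2) / max(t_half, t[1] if len(t) > 1 else 1.0))


def fit_exponential(profile: IntakeProfile, max_restarts: int = 3) -> ExpFit:
    """Nonlinear least-squares fit of the exponential model to one profile.

    The origin point (0, 0) is included and unweighted.  ``a`` starts at the
    final cumulative value, ``b`` at a half-rise moment estimate; up to
    ``max_restarts`` perturbed-``b`` restarts are tried before reporting the
    best parameters with ``converged=False``.
    """
    t, y = profile.t, profile.y
    if t.size < 10:
        raise ValueError("need at least 10 points to fit the exponential model")
    a0 = max(float(y[-1]), 1e-6)
    b0 = _moment_b0(t, y, a0)

    def residuals(theta):
        a, b = theta
        return a * (-np.expm1(-b * t)) - y

    best = None
    starts = [b0] + [b0 * f for f in (0.3, 3.0, 10.0)][:max_restarts]
    for i, b_start in enumerate(starts):
        sol = least_squares(residuals, x0=[a0, b_start],
                            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or rmse < best[2]:
            best = (sol.x[0], sol.x[1], rmse, bool(sol.success))
        if sol.success and i == 0:
            break
    a, b, rmse, ok = best
    return ExpFit(a=float(a), b=float(b), rmse=rmse, n_points=int(t.size),
                  converged=ok)
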