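"""Body-water label availability: the forcing function U(t) and its fit.

During oral heavy-water labeling the fraction of deuterium in body water
rises towards a plateau while the subject drinks labeled water and washes
out exponentially after intake stops.  The empirical description used here
is

    U(t) = f (1 - exp(-delta t)) + beta exp(-delta t)     for t <= tau
    U(t) = U(tau) exp(-delta (t - tau))                   for t >  tau

where ``f`` is the asymptotic labeled fraction, ``delta`` the body-water
turnover rate (per day), ``beta`` the plasma enrichment reached by the end
of day 0 (a loading-dose effect), and ``tau`` the length of the labeling
period in days.  The washout branch decays at the same body-water turnover
rate and is continuous at ``tau``.

``BodyWaterModel`` fits (f, beta, delta) to a saliva enrichment time
series by bounded least squares with a deterministic multistart; ``tau``
is fixed by the study design (49 days for a 7-week protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ConvergenceWarning, DomainError, InsufficientDataError

__all__ = [
    "BodyWaterCurve",
    "SalivaSeries",
    "BodyWaterModel",
    "BodyWaterFit",
    "evaluate_body_water",
]


@dataclass(frozen=True)
class BodyWaterCurve:
    """Parameterised body-water enrichment curve U(t).

    Parameters
    ----------
    f : float
        Asymptotic labeled fraction in body water (dimensionless, in [0, 1]).
    delta : float
        Body-water turnover rate, per day (> 0).
    beta : float
        Plasma enrichment at the end of day 0 (dimensionless, in [0, 1]).
    tau : float
        Length of the labeling period, days (> 0). Default 49 (7 weeks).
    """

    f: float
    delta: float
    beta: float
    tau: float = 49.0

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise DomainError(f"f must be in [0, 1], got {self.f}")
        if not 0.0 <= self.beta <= 1.0:
            raise DomainError(f"beta must be in [0, 1], got {self.beta}")
        if not self.delta > 0.0:
            raise DomainError(f"delta must be > 0, got {self.delta}")
        if not self.tau > 0.0:
            raise DomainError(f"tau must be > 0, got {self.tau}")

    def __call__(self, t):
        return evaluate_body_water(self, t)


def evaluate_body_water(curve: BodyWaterCurve, t):
    """Evaluate U(t) at time(s) ``t`` (days, >= 0).

    Returns a scalar for scalar input, an array for array input.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("body-water curve is defined for t >= 0 only")
    f, d, b, tau = curve.f, curve.delta, curve.beta, curve.tau
    labeling = f - (f - b) * np.exp(-d * t_arr)
    u_tau = f - (f - b) * np.exp(-d * tau)
    washout = u_tau * np.exp(-d * np.maximum(t_arr - tau, 0.0))
    out = np.where(t_arr <= tau, labeling, washout)
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


@dataclass(frozen=True)
class SalivaSeries:
    """Saliva deuterium enrichment time series for one volunteer."""

    volunteer_id: str
    days: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        enr = np.asarray(self.enrichment, dtype=float)
        if days.shape != enr.shape or days.ndim != 1:
            raise DomainError("days and enrichment must be 1-D and equal length")
        if np.any(np.diff(days) <= 0):
            raise DomainError("sampling days must be strictly increasing")
        if np.any(days < 0):
            raise DomainError("sampling days must be nonnegative")
        if np.any(enr < 0):
            raise DomainError("enrichments must be nonnegative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "enrichment", enr)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, volunteer_id: str) -> "SalivaSeries":
        sub = df[df["volunteer_id"] == volunteer_id].sort_values("day")
        return cls(volunteer_id, sub["day"].to_numpy(), sub["enrichment"].to_numpy())

    def __len__(self):
        return len(self.days)


@dataclass
class BodyWaterFit:
    """Result of fitting U(t) to a saliva series."""

    curve: BodyWaterCurve
    bse: dict = field(default_factory=dict)  # std. errors for f, beta, delta
    rss: float = np.nan
    converged: bool = False
    degenerate: bool = False
    n_obs: int = 0

    @property
    def params(self) -> dict:
        return {"f": self.curve.f, "beta": self.curve.beta, "delta": self.curve.delta}

    def summary(self) -> str:
        lines = [f"Body-water curve fit ({self.n_obs} saliva observations)"]
        for name in ("f", "beta", "delta"):
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:5s} = {self.params[name]:.6g}  (SE {se:.2g})")
        lines.append(f"  tau   = {self.curve.tau:g} days (fixed)")
        lines.append(f"  RSS = {self.rss:.4g}  converged = {self.converged}"
                     + ("  [degenerate]" if self.degenerate else ""))
        return "\n".join(lines)


class BodyWaterModel:
    """Least-squares model for the body-water curve given saliva data.

    ``tau`` is fixed by study design; the free parameters are
    (f, beta, delta) with bounds f, beta in [0, 1] and delta in (0, 1].
    A deterministic multistart guards against local minima.
    """

    #: free parameters, in vector order
    param_names = ("f", "beta", "delta")

    def __init__(self, series: SalivaSeries, tau: float = 49.0):
        if len(series) < 4:
            raise InsufficientDataError(
                f"need >= 4 saliva observations, got {len(series)}"
            )
        self.series = series
        self.tau = float(tau)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        f, beta, delta = theta
        curve = BodyWaterCurve(f=f, beta=beta, delta=max(delta, 1e-12), tau=self.tau)
        return curve(self.series.days) - self.series.enrichment

    def fit(self, n_starts: int = 8, seed: int = 0) -> BodyWaterFit:
        y = self.series.enrichment
        lo = np.array([0.0, 0.0, 1e-6])
        hi = np.array([1.0, 1.0, 1.0])
        # heuristic start: plateau near the max, day-0 intercept near the first
        # point, turnover on the scale of typical body-water half lives
        starts = [np.clip(np.array([max(y.max(), 1e-4), y[0], 0.1]), lo, hi)]
        rng = np.random.default_rng(seed)
        for _ in range(max(n_starts - 1, 0)):
            starts.append(lo + (hi - lo) * rng.random(3))

        best = None
        for x0 in starts:
            sol = least_squares(
                self._residuals, x0, bounds=(lo, hi),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol

        rss = float(2.0 * best.cost)
        converged = bool(best.success)
        if not converged:
            warnings.warn("body-water fit did not converge", ConvergenceWarning)
        f_hat, beta_hat, delta_hat = best.x
        curve = BodyWaterCurve(f=f_hat, beta=beta_hat, delta=max(delta_hat, 1e-12),
                               tau=self.tau)
        degenerate = f_hat < 1e-6 or y.max() <= 0
        bse = self._standard_errors(best, rss)
        return BodyWaterFit(curve=curve, bse=bse, rss=rss, converged=converged,
                            degenerate=degenerate, n_obs=len(self.series))

    def _standard_errors(self, sol, rss: float) -> dict:
        n, k = len(self.series), len(self.param_names)
        if n <= k:
            return {p: np.nan for p in self.param_names}
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - k)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return dict(zip(self.param_names, se))
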