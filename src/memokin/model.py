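"""Joint fitting of label-enrichment and telomere data per volunteer-lineage.

The estimation problem: given (i) DNA label enrichment time series for the
CD57- and CD57+ memory subsets of one volunteer-lineage, (ii) that
volunteer's fitted body-water curve U(t), and (iii) the observed mean
telomere-length difference between the subsets, estimate the five turnover
parameters

    p1, z1*, p2, z2*, mR        (all per day)

by weighted nonlinear least squares on the joint residual vector.  To let
the single telomere observation weigh against the ~16 label points, each
data type is normalised by the mean of its own observations and the label
residuals are additionally divided by the number of label points.

The optimizer is a seeded pseudo-random global search (uniform draws
inside the parameter bounds) followed by bounded derivative-based local
refinement of the best candidates — deterministic given the seed.

Usage follows the Model/Results convention::

    model = TurnoverModel(dataset, curve)
    res = model.fit()                       # full model
    res0 = model.fit(variant="constrained_p2_zero")
    comp = compare_models(res0, res)        # F test + AICc
    print(res.summary())

Standard errors come from an asymptotic covariance of the weighted
least-squares estimator — by default the sandwich form that propagates
per-data-type error variances, optionally the textbook pooled
s^2 (J'J)^-1; singular designs are reported as not-determined (NaN).
The headline statistic is the self-renewal
contribution 100 p2/(p2 + mR): the percentage of newly generated CD57+
cells produced by division within the CD57+ pool rather than by influx
from the CD57- pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import least_squares

from .bodywater import BodyWaterCurve
from .data import VolunteerDataset
from .exceptions import ConvergenceWarning, DomainError, InsufficientDataError
from .kinetics import (
    VARIANT_COINCIDENT,
    VARIANT_CONVERSION_WITHOUT_DIVISION,
    KineticParameters,
    label_fraction_trajectories,
)
from .telomere import MR_FLOOR, TelomereSettings

__all__ = [
    "FitConfig",
    "TurnoverModel",
    "TurnoverResults",
    "ModelComparison",
    "self_renewal_percentage",
    "aicc",
    "compare_aicc",
    "f_test_nested",
    "compare_models",
    "fit_nested_pair",
]

PARAM_NAMES = ("p1", "z1s", "p2", "z2s", "mR")

VARIANT_FULL = "full"
VARIANT_CONSTRAINED = "constrained_p2_zero"
VARIANT_NO_DIVISION = "conversion_without_division"
_VARIANTS = (VARIANT_FULL, VARIANT_CONSTRAINED, VARIANT_NO_DIVISION)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the joint fit.

    bounds are per-day rates; the default upper bound for the composite
    conversion rate mR is 0.40/day, for the other rates 0.20/day.
    ``n_global`` pseudo-random draws seed the global search; the
    ``n_refine`` best are polished by bounded least squares.
    """

    bounds: dict = field(default_factory=lambda: {
        "p1": (0.0, 0.20), "z1s": (0.0, 0.20),
        "p2": (0.0, 0.20), "z2s": (0.0, 0.20),
        "mR": (0.0, 0.40),
    })
    n_global: int = 2000
    n_refine: int = 3
    seed: int = 0
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    #: local refinement: "trf", "dogbox", or "hybrid" (trf, then dogbox
    #: from trf's endpoint if trf stalls).  trf crawls into the boundary
    #: optima of the constrained variant, dogbox zigzags on interior
    #: optima, so the hybrid runs both where needed
    optimizer: str = "hybrid"
    #: characteristic parameter scale (per day) for the trust region
    x_scale: float = 0.01
    #: function-evaluation cap per refinement stage
    max_nfev: int = 200
    #: "robust" propagates per-data-type error variances through the
    #: weighted Jacobian (sandwich form); "pooled" is the textbook
    #: s^2 (J'J)^-1 with a single pooled residual variance
    se_method: str = "robust"
    telomere: TelomereSettings = field(default_factory=TelomereSettings)
    bw: float = 3.5
    mr_floor: float = MR_FLOOR
    #: floor (bp) on the |observed Delta| used to normalise the telomere
    #: residual; None -> one division's worth (epsilon)
    telomere_norm_floor: float | None = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise DomainError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def delta_norm_floor(self) -> float:
        if self.telomere_norm_floor is not None:
            return self.telomere_norm_floor
        return self.telomere.epsilon

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if "telomere" in d and isinstance(d["telomere"], dict):
            d["telomere"] = TelomereSettings(**d["telomere"])
        if "bounds" in d:
            # partial bounds mappings override the defaults they name
            merged = dict(cls().bounds)
            merged.update({k: tuple(v) for k, v in d["bounds"].items()})
            d["bounds"] = merged
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def self_renewal_percentage(p2: float, mR: float) -> float:
    """Self-renewal contribution 100 p2/(p2 + mR), in percent.

    p2 and mR must share units (they cancel).  Undefined when both are 0.
    """
    if p2 < 0 or mR < 0:
        raise DomainError("p2 and mR must be nonnegative")
    if p2 == 0 and mR == 0:
        raise DomainError("self-renewal undefined when p2 = mR = 0")
    return 100.0 * p2 / (p2 + mR)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC for a least-squares fit.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    rss = max(float(rss), 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class TurnoverModel:
    """Joint label + telomere model for one volunteer-lineage.

    Parameters
    ----------
    dataset : VolunteerDataset
        Label series for both subsets; telomere observations if available
        (without them the fit is label-only and flagged).
    curve : BodyWaterCurve
        The volunteer's fitted body-water forcing function (fixed input;
        fit it first with :class:`~memokin.bodywater.BodyWaterModel`).
    config : FitConfig, optional
    """

    def __init__(self, dataset: VolunteerDataset, curve: BodyWaterCurve,
                 config: FitConfig | None = None):
        self.dataset = dataset
        self.curve = curve
        self.config = config or FitConfig()

        neg, pos = dataset.labels["CD57neg"], dataset.labels["CD57pos"]
        if len(neg) < 1 or len(pos) < 1:
            raise InsufficientDataError("need label data for both subsets")
        self._days = {"CD57neg": neg.days, "CD57pos": pos.days}
        self._obs = {"CD57neg": neg.enrichment, "CD57pos": pos.enrichment}
        all_label = np.concatenate([neg.enrichment, pos.enrichment])
        self._n_label = all_label.size
        self._label_norm = max(float(np.mean(all_label)), 1e-12) * self._n_label

        self.telomere_used = dataset.has_telomere
        self._delta_var = None
        if self.telomere_used:
            self._delta_obs = dataset.delta_obs()
            self._delta_norm = max(abs(self._delta_obs), self.config.delta_norm_floor)
            neg = dataset.telomeres["CD57neg"]
            pos = dataset.telomeres["CD57pos"]
            if (neg.lengths is not None and pos.lengths is not None
                    and neg.n_molecules > 1 and pos.n_molecules > 1):
                # sampling variance of the observed mean difference,
                # straight from the per-molecule STELA spread
                self._delta_var = float(
                    np.var(neg.lengths, ddof=1) / neg.n_molecules
                    + np.var(pos.lengths, ddof=1) / pos.n_molecules
                )
        else:
            self._delta_obs = np.nan
            self._delta_norm = np.nan

    # ------------------------------------------------------------------ #
    # residuals

    @property
    def nobs(self) -> int:
        """Fitted observations: all label points plus the telomere difference."""
        return self._n_label + (1 if self.telomere_used else 0)

    def free_names(self, variant: str = VARIANT_FULL) -> tuple[str, ...]:
        if variant not in _VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant == VARIANT_CONSTRAINED:
            return ("p1", "z1s", "z2s", "mR")
        return PARAM_NAMES

    def _theta_to_params(self, theta: np.ndarray, variant: str) -> KineticParameters:
        d = dict(zip(self.free_names(variant), theta))
        d.setdefault("p2", 0.0)
        return KineticParameters(
            p1=d["p1"], z1s=d["z1s"], p2=d["p2"], z2s=d["z2s"], mR=d["mR"],
            R=self.dataset.R if self.dataset.R else 1.0, bw=self.config.bw,
        )

    def _predicted_labels(self, params: KineticParameters, variant: str):
        kin_variant = (
            VARIANT_CONVERSION_WITHOUT_DIVISION
            if variant == VARIANT_NO_DIVISION
            else VARIANT_COINCIDENT
        )
        method = "closed" if kin_variant == VARIANT_COINCIDENT else "ode"
        out = {}
        for subset in ("CD57neg", "CD57pos"):
            traj = label_fraction_trajectories(
                params, self.curve, self._days[subset],
                method=method, variant=kin_variant,
            )
            out[subset] = traj.L1 if subset == "CD57neg" else traj.L2
        return out

    def _delta_c(self, params: KineticParameters) -> float:
        ts = self.config.telomere
        mr = max(params.mR, self.config.mr_floor)
        return ts.epsilon * (2.0 * (params.p2 - params.p1) / mr + ts.K)

    def joint_residuals(self, params: KineticParameters,
                        variant: str = VARIANT_FULL) -> np.ndarray:
        """Normalised residual vector: CD57- labels, CD57+ labels, telomere.

        Label residuals are divided by the mean observed label enrichment
        of this volunteer-lineage and by the number of label points; the
        telomere residual by |observed Delta| (floored at epsilon bp).
        """
        pred = self._predicted_labels(params, variant)
        res = [
            (pred[s] - self._obs[s]) / self._label_norm
            for s in ("CD57neg", "CD57pos")
        ]
        if self.telomere_used:
            res.append(
                np.atleast_1d(
                    (self._delta_c(params) - self._delta_obs) / self._delta_norm
                )
            )
        return np.concatenate(res)

    def _residual_vec(self, theta: np.ndarray, variant: str) -> np.ndarray:
        return self.joint_residuals(self._theta_to_params(theta, variant), variant)

    def _rss_global(self, draws: np.ndarray, variant: str) -> np.ndarray:
        """RSS of many candidate parameter vectors at once.

        The closed-form label solution broadcasts over candidates, which
        keeps the 2000-draw global search cheap; the numerically
        integrated variant falls back to a loop.
        """
        if variant == VARIANT_NO_DIVISION:
            return np.array(
                [float(np.sum(self._residual_vec(x, variant) ** 2)) for x in draws]
            )
        from .kinetics import _label_closed

        names = self.free_names(variant)
        cols = {n: draws[:, i] for i, n in enumerate(names)}
        p2 = cols.get("p2", np.zeros(len(draws)))
        bw = self.config.bw
        uptake = {"CD57neg": cols["p1"] * bw, "CD57pos": (p2 + cols["mR"]) * bw}
        loss = {"CD57neg": cols["z1s"], "CD57pos": cols["z2s"]}
        rss = np.zeros(len(draws))
        for subset in ("CD57neg", "CD57pos"):
            pred = _label_closed(
                uptake[subset][:, None], loss[subset][:, None],
                self.curve, self._days[subset],
            )
            r = (pred - self._obs[subset][None, :]) / self._label_norm
            rss += np.sum(r * r, axis=1)
        if self.telomere_used:
            ts = self.config.telomere
            mr = np.maximum(cols["mR"], self.config.mr_floor)
            dc = ts.epsilon * (2.0 * (p2 - cols["p1"]) / mr + ts.K)
            r = (dc - self._delta_obs) / self._delta_norm
            rss += r * r
        return rss

    # ------------------------------------------------------------------ #
    # fitting

    def _bounds(self, variant: str):
        names = self.free_names(variant)
        lo = np.array([self.config.bounds[n][0] for n in names])
        hi = np.array([self.config.bounds[n][1] for n in names])
        return names, lo, hi

    def fit(self, variant: str = VARIANT_FULL,
            extra_starts=None) -> "TurnoverResults":
        """Seeded global search + local least-squares refinement.

        ``extra_starts`` adds deterministic refinement starts (parameter
        vectors in the variant's free-parameter order) to the best global
        draws — e.g. the constrained optimum when fitting the full model
        of a nested pair, which enforces RSS(full) <= RSS(constrained).
        """
        names, lo, hi = self._bounds(variant)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        draws = lo + (hi - lo) * rng.random((cfg.n_global, len(names)))
        rss_draws = self._rss_global(draws, variant)
        order = np.argsort(rss_draws, kind="stable")[: max(cfg.n_refine, 1)]
        starts = [draws[idx] for idx in order]
        for x0 in extra_starts or []:
            starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))

        best = None
        for x0 in starts:
            sol = self._refine(x0, variant, lo, hi)
            if best is None or sol.cost < best.cost:
                best = sol

        rss = float(2.0 * best.cost)
        success = bool(best.success)
        if not success:
            warnings.warn(
                f"{self.dataset.key} ({variant}): fit did not converge",
                ConvergenceWarning,
            )
        tol = 1e-8 * (hi - lo)
        pinned = [
            n for n, x, a, b, t in zip(names, best.x, lo, hi, tol)
            if (x - a) < t or (b - x) < t
        ]

        se, cov = self._covariance(best.jac, best.fun, len(names))
        params = pd.Series(0.0, index=PARAM_NAMES)
        bse = pd.Series(np.nan, index=PARAM_NAMES)
        for n, x in zip(names, best.x):
            params[n] = x
        for n, s in zip(names, se):
            bse[n] = s

        return TurnoverResults(
            model=self, variant=variant, params=params, bse=bse,
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            rss=rss, nobs=self.nobs, k_params=len(names),
            success=success, pinned=pinned, telomere_used=self.telomere_used,
        )

    def _refine(self, x0: np.ndarray, variant: str, lo: np.ndarray,
                hi: np.ndarray):
        """Bounded local refinement from one start (see FitConfig.optimizer)."""
        cfg = self.config
        methods = (
            ("trf", "dogbox") if cfg.optimizer == "hybrid" else (cfg.optimizer,)
        )
        sol = least_squares(
            self._residual_vec, x0, args=(variant,), bounds=(lo, hi),
            method=methods[0], x_scale=cfg.x_scale,
            ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol, max_nfev=cfg.max_nfev,
        )
        if sol.status == 0 and len(methods) > 1:
            second = least_squares(
                self._residual_vec, sol.x, args=(variant,), bounds=(lo, hi),
                method=methods[1], x_scale=cfg.x_scale,
                ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol,
                max_nfev=cfg.max_nfev,
            )
            if second.cost <= sol.cost:
                sol = second
        return sol

    def _covariance(self, jac: np.ndarray, resid: np.ndarray, k: int,
                    method: str | None = None):
        """Asymptotic covariance of the weighted LS estimates.

        "pooled" is s^2 (J'J)^-1 with s^2 = RSS/(n - k): valid when every
        weighted residual shares one error variance.  "robust" (default)
        keeps the same point estimates but propagates per-data-type error
        variances — label noise estimated from the label residuals, the
        telomere-difference variance from the per-molecule spread —
        through the sandwich (J'J)^-1 J' Sigma J (J'J)^-1.  The joint
        weighting makes the telomere residual orders of magnitude noisier
        than a label residual, which the pooled form cannot see.
        """
        method = method or self.config.se_method
        n = self.nobs
        nan = np.full(k, np.nan), np.full((k, k), np.nan)
        if n <= k:
            return nan
        jtj = jac.T @ jac
        # singular or near-singular designs -> not determined (N/D)
        if not np.all(np.isfinite(jtj)) or np.linalg.cond(jtj) > 1e12:
            return nan
        ainv = np.linalg.inv(jtj)
        rss = float(np.sum(resid**2))
        if method == "robust" and self.telomere_used and self._delta_var is None:
            method = "pooled"  # no molecule-level spread to propagate
        if method == "pooled":
            cov = ainv * rss / (n - k)
        elif method == "robust":
            nl = self._n_label
            raw_label = resid[:nl] * self._label_norm
            sigma2_label = float(np.sum(raw_label**2)) / max(nl - k, 1)
            var_rows = np.full(resid.size, sigma2_label / self._label_norm**2)
            if self.telomere_used:
                var_rows[-1] = self._delta_var / self._delta_norm**2
            cov = ainv @ (jac.T * var_rows) @ jac @ ainv
        else:
            raise ValueError(f"unknown se_method {method!r}")
        return np.sqrt(np.clip(np.diag(cov), 0.0, None)), cov

    def asymptotic_standard_errors(
        self, params: KineticParameters, variant: str = VARIANT_FULL,
        method: str | None = None,
    ) -> pd.Series:
        """Asymptotic standard errors at a given parameter point.

        Finite-difference Jacobian of the joint residuals; NaN entries
        mean "not determined" (n <= k or singular J'J).  ``method``
        overrides the configured covariance form ("robust" or "pooled").
        """
        names, lo, hi = self._bounds(variant)
        theta = np.array([getattr(params, n) for n in names])
        r0 = self._residual_vec(theta, variant)
        jac = np.empty((r0.size, theta.size))
        for j in range(theta.size):
            h = 1e-7 * max(abs(theta[j]), 1e-4)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            jac[:, j] = (
                self._residual_vec(tp, variant) - self._residual_vec(tm, variant)
            ) / (2 * h)
        se, _ = self._covariance(jac, r0, theta.size, method=method)
        return pd.Series(se, index=names)


@dataclass
class TurnoverResults:
    """Estimates and diagnostics from :meth:`TurnoverModel.fit`.

    ``params`` and ``bse`` are per-day rates over all five parameter names
    (a parameter fixed by the variant has bse NaN); ``summary()`` reports
    in percent per day.
    """

    model: TurnoverModel
    variant: str
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    rss: float
    nobs: int
    k_params: int
    success: bool
    pinned: list
    telomere_used: bool

    @property
    def kinetic_parameters(self) -> KineticParameters:
        return KineticParameters(
            p1=self.params["p1"], z1s=self.params["z1s"], p2=self.params["p2"],
            z2s=self.params["z2s"], mR=self.params["mR"],
            R=self.model.dataset.R if self.model.dataset.R else 1.0,
            bw=self.model.config.bw,
        )

    @property
    def self_renewal_pct(self) -> float:
        """100 p2/(p2 + mR); NaN when both rates are estimated as 0."""
        p2, mr = self.params["p2"], self.params["mR"]
        if p2 == 0 and mr == 0:
            return np.nan
        return self_renewal_percentage(p2, mr)

    @property
    def delta_c(self) -> float:
        """Fitted steady-state telomere-length difference (bp)."""
        return self.model._delta_c(self.kinetic_parameters)

    @property
    def delta_obs(self) -> float:
        return self.model._delta_obs

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals estimate +/- z_{1-alpha/2} SE (per day)."""
        zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - zcrit * self.bse,
                "upper": self.params + zcrit * self.bse,
            }
        )

    def predict(self, times=None) -> pd.DataFrame:
        """Fitted label trajectories on a day grid (default dense 0..126)."""
        if times is None:
            times = np.linspace(0.0, 126.0, 253)
        kin_variant = (
            VARIANT_CONVERSION_WITHOUT_DIVISION
            if self.variant == VARIANT_NO_DIVISION
            else VARIANT_COINCIDENT
        )
        method = "closed" if kin_variant == VARIANT_COINCIDENT else "ode"
        traj = label_fraction_trajectories(
            self.kinetic_parameters, self.model.curve, times,
            method=method, variant=kin_variant,
        )
        return pd.DataFrame({"day": traj.times, "L1": traj.L1, "L2": traj.L2})

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            f"Joint turnover fit — volunteer {ds.volunteer_id}, "
            f"{ds.lineage} lineage (variant: {self.variant})",
            f"  n = {self.nobs} ({self.model._n_label} label"
            + (" + 1 telomere)" if self.telomere_used
               else " points; no telomere data)"),
            f"  k = {self.k_params}, RSS = {self.rss:.6g}, "
            f"converged = {self.success}"
            + (f", at bounds: {self.pinned}" if self.pinned else ""),
            "  parameter   estimate (%/day)   SE (%/day)",
        ]
        for name in PARAM_NAMES:
            est = 100.0 * self.params[name]
            se = 100.0 * self.bse[name]
            se_txt = "N/D" if np.isnan(se) else f"{se:.2f}"
            fixed = " (fixed)" if (
                name == "p2" and self.variant == VARIANT_CONSTRAINED
            ) else ""
            lines.append(f"  {name:10s}  {est:16.2f}   {se_txt}{fixed}")
        sr = self.self_renewal_pct
        sr_txt = "undefined" if np.isnan(sr) else f"{sr:.0f}%"
        lines.append(f"  Self-renewal contribution 100 p2/(p2+mR): {sr_txt}")
        if self.telomere_used:
            lines.append(
                f"  Telomere difference: fitted Delta_C = {self.delta_c:.0f} bp, "
                f"observed = {self.delta_obs:.0f} bp"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_fit

        return plot_fit(self, ax=ax)


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of the p2 = 0 model against the full model."""

    F: float
    p_value: float
    aicc_full: float = np.nan
    aicc_constrained: float = np.nan

    @property
    def delta_aicc(self) -> float:
        """AICc(constrained) - AICc(full); large positive favours the full model."""
        return self.aicc_constrained - self.aicc_full


def fit_nested_pair(model: TurnoverModel):
    """Fit the constrained (p2 = 0) and full models as a proper nested pair.

    The constrained optimum seeds an extra refinement start of the full
    fit (with p2 = 0), so the full model can never end up worse than the
    sub-model it contains.  Returns (constrained, full, comparison).
    """
    res0 = model.fit(VARIANT_CONSTRAINED)
    start_full = [res0.params[n] for n in model.free_names(VARIANT_FULL)]
    res1 = model.fit(VARIANT_FULL, extra_starts=[start_full])
    return res0, res1, compare_models(res0, res1)


def f_test_nested(fit_constrained: TurnoverResults,
                  fit_full: TurnoverResults) -> ModelComparison:
    """F test of the constrained (p2 = 0) against the full model.

    F = ((RSS0 - RSS1)/(k1 - k0)) / (RSS1/(n - k1)), referred to
    F(k1-k0, n-k1).  RSS0 < RSS1 (an optimizer artifact) is clipped to
    F = 0 with a warning.
    """
    n = fit_full.nobs
    if fit_constrained.nobs != n:
        raise DomainError("nested fits must share the dataset (equal n)")
    dk = fit_full.k_params - fit_constrained.k_params
    if dk != 1:
        raise DomainError(
            f"constrained model must have exactly one fewer parameter, got dk={dk}"
        )
    rss0, rss1 = fit_constrained.rss, fit_full.rss
    dfd = n - fit_full.k_params
    if dfd <= 0:
        raise DomainError("no residual degrees of freedom for the F test")
    if rss0 < rss1:
        warnings.warn(
            "constrained RSS below full RSS (optimizer artifact); F clipped to 0",
            ConvergenceWarning,
        )
        return ModelComparison(F=0.0, p_value=1.0)
    if rss1 <= 0.0:
        return ModelComparison(F=np.inf, p_value=0.0)
    f_stat = ((rss0 - rss1) / dk) / (rss1 / dfd)
    p = float(scipy.stats.f.sf(f_stat, dk, dfd))
    return ModelComparison(F=float(f_stat), p_value=p)


def compare_aicc(fit_constrained: TurnoverResults,
                 fit_full: TurnoverResults) -> float:
    """AICc(constrained) - AICc(full); positive favours the full model."""
    return (
        aicc(fit_constrained.rss, fit_constrained.nobs, fit_constrained.k_params)
        - aicc(fit_full.rss, fit_full.nobs, fit_full.k_params)
    )


def compare_models(fit_constrained: TurnoverResults,
                   fit_full: TurnoverResults) -> ModelComparison:
    """Full nested comparison: F test plus AICc for both models."""
    partial = f_test_nested(fit_constrained, fit_full)
    return ModelComparison(
        F=partial.F, p_value=partial.p_value,
        aicc_full=aicc(fit_full.rss, fit_full.nobs, fit_full.k_params),
        aicc_constrained=aicc(
            fit_constrained.rss, fit_constrained.nobs, fit_constrained.k_params
        ),
    )
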