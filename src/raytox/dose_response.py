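"""Single-chemical log-logistic dose-response modelling.

The quantal endpoint is 48-h immobilization of *Daphnia magna*; the modelled
response is the percentage of mobile animals, which declines from the control
level ``u_max`` toward zero as concentration increases:

    y(c) = u_max / (1 + (c / EC50)**beta)

This is the three-parameter log-logistic curve with lower asymptote fixed at
zero (full immobilization is achievable).  ``u_max`` is the fitted control
response on the percent scale (the quantity some reports call C_max), ``beta``
the dimensionless slope at the EC50, and ``ec50`` the median-effect
concentration in the chemical's native unit.

Fitting is least squares on replicate-level percent-mobile values with a
bounded multi-start optimizer; confidence intervals for the EC50 come from a
nonparametric bootstrap that resamples replicate wells within treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "LogLogisticParams",
    "QuantalObservation",
    "SingleFit",
    "FitConfig",
    "NonIdentifiableError",
    "predict_mobility",
    "effective_concentration",
    "fit_single",
]


class NonIdentifiableError(ValueError):
    """Raised when the data carry no effect gradient to estimate from."""


@dataclass(frozen=True)
class LogLogisticParams:
    """One chemical's dose-response triple.

    Attributes
    ----------
    u_max : float
        Percent mobile in the control, 0 < u_max <= 100.
    beta : float
        Dimensionless slope, > 0.
    ec50 : float
        Median-effect concentration in the chemical's native unit, > 0.
    unit_label : str
        Free-text unit of ``ec50`` (e.g. "μg/L" or "mg/L").
    """

    u_max: float
    beta: float
    ec50: float
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.u_max <= 100.0:
            raise ValueError(f"u_max must be in (0, 100], got {self.u_max}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.ec50 > 0.0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")


@dataclass(frozen=True)
class QuantalObservation:
    """One replicate well: exposed/immobilized counts at a concentration point.

    ``concentrations`` holds one value per chemical in native units; for a
    single-chemical record it has length 1, for a binary mixture length 2
    (either entry may be zero).
    """

    concentrations: tuple[float, ...]
    replicate_id: str
    n_exposed: int
    n_immobile: int
    treatment_id: str

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError(f"negative concentration in {self.concentrations}")
        if self.n_exposed <= 0:
            raise ValueError("n_exposed must be > 0")
        if not 0 <= self.n_immobile <= self.n_exposed:
            raise ValueError(
                f"n_immobile={self.n_immobile} outside [0, {self.n_exposed}]"
            )

    @property
    def percent_mobile(self) -> float:
        return 100.0 * (1.0 - self.n_immobile / self.n_exposed)


@dataclass
class FitConfig:
    """Tuning knobs for the single-chemical fitter."""

    n_starts: int = 16
    bootstrap_draws: int = 999
    bootstrap_seed: int = 0
    beta_bounds: tuple[float, float] = (0.1, 20.0)
    u_max_start_bounds: tuple[float, float] = (80.0, 100.0)
    ftol: float = 1e-10


@dataclass
class SingleFit:
    """Result of a single-chemical least-squares fit."""

    params: LogLogisticParams
    ss: float
    ci_ec50: tuple[float, float] | None
    n_obs: int
    bootstrap_failures: int = 0


def predict_mobility(params: LogLogisticParams, c: float | np.ndarray) -> float | np.ndarray:
    """Percent of mobile animals predicted at concentration ``c``.

    ``y(0) = u_max`` exactly and ``y(ec50) = u_max / 2`` exactly; the curve is
    strictly decreasing in ``c``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        y = params.u_max / (1.0 + (c / params.ec50) ** params.beta)
    return float(y) if y.ndim == 0 else y


def effective_concentration(params: LogLogisticParams, effect_percent: float) -> float:
    """Concentration reducing mobility by ``effect_percent`` percent of u_max.

    Inverse of :func:`predict_mobility`: ECx = EC50 * (x / (100 - x))**(1/beta),
    so ``predict_mobility(params, ECx) == u_max * (1 - x/100)``.  x = 50
    returns the EC50 exactly.
    """
    x = effect_percent
    if not 0.0 < x < 100.0:
        raise ValueError(f"effect percent must lie in (0, 100), got {x}")
    return params.ec50 * (x / (100.0 - x)) ** (1.0 / params.beta)


# ---------------------------------------------------------------------------
# Least-squares fitting


def _residuals(theta: np.ndarray, conc: np.ndarray, pct: np.ndarray) -> np.ndarray:
    u_max, log_beta, log_ec50 = theta
    beta, ec50 = np.exp(log_beta), np.exp(log_ec50)
    with np.errstate(divide="ignore"):
        pred = u_max / (1.0 + (conc / ec50) ** beta)
    return pred - pct


def _single_chem_arrays(
    observations: Sequence[QuantalObservation],
) -> tuple[np.ndarray, np.ndarray]:
    conc = np.array([obs.concentrations[0] for obs in observations], dtype=float)
    pct = np.array([obs.percent_mobile for obs in observations], dtype=float)
    return conc, pct


def _ls_fit(
    conc: np.ndarray,
    pct: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Multi-start bounded least squares; returns best (u_max, beta, ec50), SS."""
    pos = conc[conc > 0]
    lb_ec, ub_ec = pos.min() / 10.0, pos.max() * 10.0
    lb = np.array([1.0, np.log(config.beta_bounds[0]), np.log(lb_ec)])
    ub = np.array([100.0, np.log(config.beta_bounds[1]), np.log(ub_ec)])

    sampler = qmc.LatinHypercube(d=3, seed=rng)
    unit = sampler.random(max(config.n_starts, 1))
    # u_max starts restricted to the plausible control band; bounds stay wide.
    start_lo = np.array([config.u_max_start_bounds[0], lb[1], lb[2]])
    start_hi = np.array([config.u_max_start_bounds[1], ub[1], ub[2]])
    starts = qmc.scale(unit, start_lo, start_hi)

    best_theta, best_ss = None, np.inf
    for theta0 in starts:
        try:
            res = least_squares(
                _residuals, theta0, args=(conc, pct), bounds=(lb, ub),
                method="trf", ftol=config.ftol, xtol=1e-12, gtol=1e-12,
            )
        except ValueError:
            continue
        ss = float(np.sum(res.fun**2))
        if ss < best_ss:
            best_ss, best_theta = ss, res.x
    if best_theta is None:
        raise RuntimeError("all optimizer starts failed")
    return best_theta, best_ss


def fit_single(
    observations: Sequence[QuantalObservation],
    config: FitConfig | None = None,
) -> SingleFit:
    """Fit the three-parameter log-logistic curve to replicate-level data.

    The objective is the sum of squared residuals on the percent-mobile scale
    over all replicate wells.  A missing control triggers a warning (u_max is
    then fitted unconstrained by any zero-dose record); data with no effect
    gradient raise :class:`NonIdentifiableError`.

    The EC50 confidence interval is a percentile bootstrap: replicate wells
    are resampled with replacement within each treatment, the curve refitted
    (single start at the point estimate), and the 2.5/97.5 percentiles taken.
    ``config.bootstrap_draws = 0`` skips the bootstrap (``ci_ec50 = None``).
    """
    config = config or FitConfig()
    if len(observations) == 0:
        raise ValueError("no observations")
    if any(len(obs.concentrations) != 1 for obs in observations):
        raise ValueError("fit_single expects single-chemical observations")
    conc, pct = _single_chem_arrays(observations)
    if len(np.unique(conc[conc > 0])) < 3:
        raise ValueError("need at least 3 distinct nonzero concentrations")
    if np.ptp(pct) == 0.0:
        raise NonIdentifiableError(
            "all responses identical: no effect gradient to fit"
        )
    if not np.any(conc == 0):
        warnings.warn("no control (zero-dose) observations; u_max fitted "
                      "without a control anchor", stacklevel=2)

    rng = np.random.default_rng(config.bootstrap_seed)
    theta, ss = _ls_fit(conc, pct, config, rng)
    params = LogLogisticParams(
        u_max=float(theta[0]), beta=float(np.exp(theta[1])),
        ec50=float(np.exp(theta[2])),
    )

    ci = None
    n_fail = 0
    if config.bootstrap_draws > 0:
        ci, n_fail = _bootstrap_ci_ec50(observations, theta, config, rng)
        # The point estimate can fall marginally outside the percentile band
        # in pathological resamples; widen to keep the interval honest.
        ci = (min(ci[0], params.ec50), max(ci[1], params.ec50))
    return SingleFit(params=params, ss=ss, ci_ec50=ci,
                     n_obs=len(observations), bootstrap_failures=n_fail)


def _bootstrap_ci_ec50(
    observations: Sequence[QuantalObservation],
    theta_hat: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], int]:
    by_treatment: dict[str, list[QuantalObservation]] = {}
    for obs in observations:
        by_treatment.setdefault(obs.treatment_id, []).append(obs)
    groups = [_single_chem_arrays(g) for g in by_treatment.values()]

    lb = np.array([1.0, np.log(config.beta_bounds[0]), theta_hat[2] - np.log(1e4)])
    ub = np.array([100.0, np.log(config.beta_bounds[1]), theta_hat[2] + np.log(1e4)])
    draws = np.empty(config.bootstrap_draws)
    n_fail = 0
    for i in range(config.bootstrap_draws):
        cs, ps = [], []
        for conc_g, pct_g in groups:
            idx = rng.integers(0, len(conc_g), size=len(conc_g))
            cs.append(conc_g[idx])
            ps.append(pct_g[idx])
        conc_b, pct_b = np.concatenate(cs), np.concatenate(ps)
        if np.ptp(pct_b) == 0.0:
            n_fail += 1
            draws[i] = np.nan
            continue
        try:
            res = least_squares(
                _residuals, theta_hat, args=(conc_b, pct_b), bounds=(lb, ub),
                method="trf", ftol=1e-8, xtol=1e-10,
            )
            draws[i] = np.exp(res.x[2])
        except ValueError:
            n_fail += 1
            draws[i] = np.nan
    ok = draws[~np.isnan(draws)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return (float(lo), float(hi)), n_fail
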