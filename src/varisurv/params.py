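"""Population parameters, baseline hazards, and visit schedules.

The generating model couples a linear mixed model with subject-specific
residual variance (a mixed-effects location-scale model) to a proportional
hazards model through shared latent effects:

* longitudinal:  Y_ij = beta0 + beta1*t_ij + beta_cov.X_i + I_i + S_i*t_ij + e_ij,
  with e_ij ~ N(0, exp(mu_v + U_i)) and (I_i, S_i, U_i) ~ MVN(0, Sigma);
* survival hazard:  lambda_i(t) = lambda0(t) * exp(alpha0 + alpha_cov.Z_i
  + gamma1*I_i + gamma2*S_i + gamma3*U_i).

``gamma3`` is the prognostic effect of within-subject variability, the
quantity of interest throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class SigmaValidationError(ValueError):
    """Raised when the random-effects covariance is not positive definite."""


def build_sigma(
    sigma_i: float,
    sigma_s: float,
    sigma_v: float,
    rho_12: float = 0.0,
    rho_13: float = 0.0,
    rho_23: float = 0.0,
) -> np.ndarray:
    """Assemble the 3x3 covariance of (I, S, U) from SDs and correlations.

    Parameters
    ----------
    sigma_i, sigma_s, sigma_v
        Standard deviations of the random intercept, slope, and
        log-residual-variance deviation. Must be positive.
    rho_12, rho_13, rho_23
        Correlations among (I, S), (I, U) and (S, U); each in (-1, 1).

    Returns
    -------
    ndarray of shape (3, 3), symmetric positive definite.

    Raises
    ------
    SigmaValidationError
        If any SD is nonpositive, any |rho| >= 1, or the implied matrix is
        not positive definite (possible when all three correlations are
        large); the message names the offending leading principal minor.
    """
    sds = np.asarray([sigma_i, sigma_s, sigma_v], dtype=float)
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        raise SigmaValidationError(f"standard deviations must be positive, got {sds}")
    rhos = np.asarray([rho_12, rho_13, rho_23], dtype=float)
    if np.any(np.abs(rhos) >= 1):
        raise SigmaValidationError(f"correlations must satisfy |rho| < 1, got {rhos}")
    corr = np.array(
        [
            [1.0, rho_12, rho_13],
            [rho_12, 1.0, rho_23],
            [rho_13, rho_23, 1.0],
        ]
    )
    sigma = corr * np.outer(sds, sds)
    # Sylvester's criterion: check leading principal minors so the error can
    # name the first one that fails.
    for k in (1, 2, 3):
        minor = np.linalg.det(sigma[:k, :k])
        if minor <= 0:
            raise SigmaValidationError(
                f"covariance not positive definite: leading principal minor "
                f"of order {k} is {minor:.3e} <= 0"
            )
    return sigma


@dataclass(frozen=True)
class PiecewiseHazard:
    """Step-function baseline hazard.

    ``cutpoints`` start at 0 and are strictly increasing; ``heights`` gives
    the hazard on each interval, the last one extending to infinity.
    """

    cutpoints: tuple[float, ...]
    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        cp = np.asarray(self.cutpoints, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if cp.size == 0 or cp[0] != 0.0:
            raise ValueError("cutpoints must start at 0")
        if cp.size > 1 and np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if h.size != cp.size:
            raise ValueError("need one height per interval")
        if np.any(h <= 0):
            raise ValueError("hazard heights must be positive")

    @property
    def n_intervals(self) -> int:
        return len(self.heights)

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """Baseline cumulative hazard Lambda0(t) for t >= 0."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cp = np.asarray(self.cutpoints)
        h = np.asarray(self.heights)
        # exposure of [0, t] to each interval
        upper = np.append(cp[1:], np.inf)
        expo = np.clip(t[:, None], None, upper[None, :]) - cp[None, :]
        np.clip(expo, 0.0, None, out=expo)
        return expo @ h

    def inverse_cumulative(self, h_target: np.ndarray) -> np.ndarray:
        """Invert the cumulative hazard (sequential interval inversion)."""
        h_target = np.atleast_1d(np.asarray(h_target, dtype=float))
        cp = np.asarray(self.cutpoints)
        rates = np.asarray(self.heights)
        cum_at_cp = np.concatenate([[0.0], self.cumulative(cp[1:])]) if cp.size > 1 else np.zeros(1)
        idx = np.searchsorted(cum_at_cp, h_target, side="right") - 1
        idx = np.clip(idx, 0, len(rates) - 1)
        return cp[idx] + (h_target - cum_at_cp[idx]) / rates[idx]

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(np.asarray(self.cutpoints), t, side="right") - 1
        idx = np.clip(idx, 0, self.n_intervals - 1)
        return np.asarray(self.heights)[idx]


@dataclass(frozen=True)
class PopulationParams:
    """All generating parameters of the joint model.

    Defaults are the constants of the package's reference simulation design
    (an eye-pressure-like biomarker around 25 units with a standard-normal
    baseline covariate on both processes).
    """

    beta0: float = 25.0
    beta1: float = 0.0
    beta_cov: tuple[float, ...] = (1.0,)
    mu_v: float = 1.5
    sigma_i: float = 2.5
    sigma_s: float = 0.4
    sigma_v: float = 0.7
    rho_12: float = 0.1
    rho_13: float = 0.2
    rho_23: float = 0.2
    alpha0: float = 0.0
    alpha_cov: tuple[float, ...] = (0.5,)
    gamma1: float = 0.2
    gamma2: float = 1.0
    gamma3: float = 0.0
    baseline_hazard: float | PiecewiseHazard = 0.05
    censor_low: float = 1.0
    censor_high: float = 8.0

    def __post_init__(self) -> None:
        build_sigma(self.sigma_i, self.sigma_s, self.sigma_v,
                    self.rho_12, self.rho_13, self.rho_23)
        if not self.censor_low < self.censor_high:
            raise ValueError("censor_low must be below censor_high")
        if isinstance(self.baseline_hazard, (int, float)) and self.baseline_hazard <= 0:
            raise ValueError("baseline hazard rate must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return build_sigma(self.sigma_i, self.sigma_s, self.sigma_v,
                           self.rho_12, self.rho_13, self.rho_23)

    @property
    def hazard(self) -> PiecewiseHazard:
        """The baseline hazard as a (possibly one-piece) step function."""
        if isinstance(self.baseline_hazard, PiecewiseHazard):
            return self.baseline_hazard
        return PiecewiseHazard((0.0,), (float(self.baseline_hazard),))

    def with_(self, **changes) -> "PopulationParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class VisitSchedule:
    """Arithmetic grid of measurement times from -lead_in to last_visit_time.

    The lead-in period guarantees every subject a minimum number of readings
    before survival follow-up starts at time 0: a semi-annual schedule with
    a 1-year lead-in yields visits {-1, -0.5, 0, 0.5, ..., 5}.
    """

    lead_in_years: float = 1.0
    visit_interval: float = 0.5
    last_visit_time: float = 5.0

    def __post_init__(self) -> None:
        if self.lead_in_years < 0:
            raise ValueError("lead_in_years must be >= 0")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if self.last_visit_time < 0:
            raise ValueError("last_visit_time must be >= 0")
        n_lead = self.lead_in_years / self.visit_interval
        if abs(n_lead - round(n_lead)) > 1e-9:
            raise ValueError("lead_in_years must be a multiple of visit_interval")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.lead_in_years + self.last_visit_time) / self.visit_interval))
        return -self.lead_in_years + self.visit_interval * np.arange(n + 1)

    @property
    def n_baseline_visits(self) -> int:
        """Number of visits at or before time 0."""
        return int(np.sum(self.times <= 1e-12))
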