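"""Synthetic data from the shared-effects joint model.

Generates linked longitudinal panels and survival tables under configurable
scenarios: visit schedules with lead-in periods, uniform censoring, and
truncation of longitudinal follow-up at the event/censoring time. The
generator emulates an eye-pressure-style cohort (values around 24-25 units,
semi-annual or quarterly visits over up to 5 years, ~80% censoring).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import PopulationParams, VisitSchedule, build_sigma


@dataclass(frozen=True)
class SimulatedDataset:
    """Linked longitudinal panel + survival table for one simulated cohort.

    ``panel`` has columns (subject_id, time, value); ``survival`` has
    (subject_id, time, event); ``covariates`` one row per subject with the
    baseline covariate columns (x0, x1, ...); ``effects`` retains the true
    latent triples (intercept, slope, log_var) for oracle tests only.
    """

    panel: pd.DataFrame
    survival: pd.DataFrame
    covariates: pd.DataFrame
    effects: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def censored_fraction(self) -> float:
        return float(1.0 - self.survival["event"].mean())


def draw_subject_effects(params: PopulationParams, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. MVN(0, Sigma) triples (I_i, S_i, U_i), shape (n, 3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma = params.sigma
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, 3)) @ chol.T


def _covariate_matrix(covariates) -> np.ndarray:
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return z


def log_hazard_multiplier(params: PopulationParams, effects: np.ndarray,
                          z) -> np.ndarray:
    """Subject-level log relative hazard: alpha0 + alpha.Z + gamma.(I,S,U)."""
    z = _covariate_matrix(z)
    gammas = np.array([params.gamma1, params.gamma2, params.gamma3])
    return (params.alpha0 + z @ np.asarray(params.alpha_cov, dtype=float)
            + effects @ gammas)


def simulate_survival(params: PopulationParams, effects: np.ndarray, z,
                      rng: np.random.Generator,
                      censoring: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observed time T_i, event indicator) per subject.

    The event time inverts the cumulative hazard m_i * Lambda0(t), with
    m_i = exp(alpha0 + alpha.Z_i + gamma1 I_i + gamma2 S_i + gamma3 U_i);
    censoring is Uniform(censor_low, censor_high) independent of the event.
    """
    n = effects.shape[0]
    eta = log_hazard_multiplier(params, effects, z)
    e = rng.exponential(size=n)
    d = params.hazard.inverse_cumulative(e * np.exp(-eta))
    if not censoring:
        return d, np.ones(n, dtype=int)
    c = rng.uniform(params.censor_low, params.censor_high, size=n)
    t = np.minimum(d, c)
    delta = (d <= c).astype(int)
    return t, delta


def simulate_longitudinal(params: PopulationParams, effects: np.ndarray, x,
                          schedule: VisitSchedule, t_obs: np.ndarray,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Generate the longitudinal panel on the visit grid.

    Every lead-in visit (time <= 0) is retained; a positive-time visit is
    retained only while the subject is under observation (time <= T_i,
    closed boundary) and before the schedule ends.
    """
    times = schedule.times
    if times.size == 0:
        raise ValueError("empty visit schedule")
    x = _covariate_matrix(x)
    n = effects.shape[0]
    beta_cov = np.asarray(params.beta_cov, dtype=float)
    fixed_part = params.beta0 + x @ beta_cov  # (n,)
    sd = np.exp(0.5 * (params.mu_v + effects[:, 2]))  # residual SD per subject

    keep = (times[None, :] <= 1e-12) | (times[None, :] <= np.asarray(t_obs)[:, None])
    noise = rng.standard_normal((n, times.size)) * sd[:, None]
    values = (fixed_part[:, None]
              + (params.beta1 + effects[:, 1][:, None]) * times[None, :]
              + effects[:, 0][:, None] + noise)
    sid = np.repeat(np.arange(n), times.size)[keep.ravel()]
    return pd.DataFrame({
        "subject_id": sid,
        "time": np.tile(times, n)[keep.ravel()],
        "value": values.ravel()[keep.ravel()],
    })


def simulate_dataset(params: PopulationParams, schedule: VisitSchedule,
                     n_subjects: int, rng: np.random.Generator | int,
                     n_covariates: int = 1) -> SimulatedDataset:
    """Generate a complete linked cohort.

    The single baseline covariate (default) is standard normal and enters
    both sub-models (X_i = Z_i); additional independent standard-normal
    covariates can be requested for user-defined designs.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = rng.standard_normal((n_subjects, n_covariates))
    effects = draw_subject_effects(params, n_subjects, rng)
    t_obs, delta = simulate_survival(params, effects, x, rng)
    panel = simulate_longitudinal(params, effects, x, schedule, t_obs, rng)
    sid = np.arange(n_subjects)
    surv = pd.DataFrame({"subject_id": sid, "time": t_obs, "event": delta})
    cov = pd.DataFrame(x, columns=[f"x{j}" for j in range(n_covariates)])
    cov.insert(0, "subject_id", sid)
    eff = pd.DataFrame(effects, columns=["intercept", "slope", "log_var"])
    eff.insert(0, "subject_id", sid)
    return SimulatedDataset(panel=panel, survival=surv, covariates=cov, effects=eff)


def calibrate_baseline_rate(params: PopulationParams,
                            target_censor_fraction: float = 0.80,
                            n_pilot: int = 20000,
                            rng: np.random.Generator | int = 0,
                            tol: float = 0.02) -> float:
    """Find a constant baseline rate giving the target censored fraction.

    Uses common random numbers: one pilot draw of subject effects,
    covariates, unit exponentials and censoring times, then solves for the
    rate by root finding on the (monotone, deterministic-given-seed) pilot
    censored fraction. Raises if the target is unattainable within the
    censoring bounds.
    """
    if not 0.0 < target_censor_fraction < 1.0:
        raise ValueError("target censored fraction must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = rng.standard_normal((n_pilot, len(params.beta_cov)))
    effects = draw_subject_effects(params, n_pilot, rng)
    eta = log_hazard_multiplier(params, effects, x)
    e = rng.exponential(size=n_pilot)
    c = rng.uniform(params.censor_low, params.censor_high, size=n_pilot)

    def censored_fraction(log_rate: float) -> float:
        d = e * np.exp(-eta - log_rate)  # event times under exponential hazard
        return float(np.mean(d > c))

    lo, hi = -12.0, 6.0
    f_lo, f_hi = censored_fraction(lo), censored_fraction(hi)
    # censored fraction decreases in the rate: f(lo) is the max attainable
    if not (f_hi < target_censor_fraction < f_lo):
        raise ValueError(
            f"target {target_censor_fraction} unattainable: pilot censored "
            f"fraction ranges ({f_hi:.3f}, {f_lo:.3f}) over plausible rates"
        )
    log_rate = brentq(lambda lr: censored_fraction(lr) - target_censor_fraction,
                      lo, hi, xtol=1e-6)
    achieved = censored_fraction(log_rate)
    if abs(achieved - target_censor_fraction) > tol:
        raise ValueError(
            f"calibration failed: achieved {achieved:.3f} vs target "
            f"{target_censor_fraction:.3f}"
        )
    return float(np.exp(log_rate))


def write_dataset(ds: SimulatedDataset, prefix: str) -> None:
    """Write panel/survival/covariates as long-format CSVs under a prefix."""
    ds.panel.to_csv(f"{prefix}_longitudinal.csv", index=False)
    ds.survival.to_csv(f"{prefix}_survival.csv", index=False)
    ds.covariates.to_csv(f"{prefix}_covariates.csv", index=False)


def read_dataset(prefix: str) -> SimulatedDataset:
    panel = pd.read_csv(f"{prefix}_longitudinal.csv")
    surv = pd.read_csv(f"{prefix}_survival.csv")
    cov = pd.read_csv(f"{prefix}_covariates.csv")
    eff = pd.DataFrame({"subject_id": surv["subject_id"]})
    return SimulatedDataset(panel=panel, survival=surv, covariates=cov, effects=eff)
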