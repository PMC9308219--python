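"""Bayesian mixed-effects location-scale model for the longitudinal data.

The measurement model alone: random intercept, slope, and log residual
variance per subject with a full 3x3 covariance among the latent triple.
This is stage 1 of regression calibration — its per-subject posterior means
replace the error-laden sample summaries in the second-stage Cox model.
Because the fit borrows strength across subjects, no minimum-measurement
rule applies.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._gibbs import GibbsSampler, LongitudinalStats
from .mcmc import MCMCConfig, PosteriorSummary, PriorSpec, summarize_chains

CORE_PARAM_NAMES = ["mu_v", "sigma_i", "sigma_s", "sigma_v",
                    "rho_12", "rho_13", "rho_23"]


def _param_names(stats: LongitudinalStats, cov_names) -> list[str]:
    return (["beta0", "beta1"] + [f"beta_{c}" for c in cov_names]
            + CORE_PARAM_NAMES)


def _run_chains(stats, priors, config, cov_names, survival=None,
                active_gamma=(True, True, True), surv_names=(),
                prior_only=False) -> PosteriorSummary:
    names = _param_names(stats, cov_names) + list(surv_names)
    chain_draws = []
    eff_sum = np.zeros((stats.n_subjects, 3))
    eff_sumsq = np.zeros((stats.n_subjects, 3))
    n_eff_total = 0
    acc = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, c]))
        sampler = GibbsSampler(stats, priors, rng, survival=survival,
                               active_gamma=active_gamma,
                               prior_only=prior_only)
        draws, es, esq, ne = sampler.run(config, names)
        chain_draws.append(draws)
        eff_sum += es
        eff_sumsq += esq
        n_eff_total += ne
        acc[f"chain_{c}"] = dict(sampler.acc)
    params, pooled = summarize_chains(chain_draws, config.rhat_threshold)
    mean = eff_sum / n_eff_total
    var = np.maximum(eff_sumsq / n_eff_total - mean ** 2, 0.0)
    effects = pd.DataFrame({
        "subject_id": stats.subject_ids,
        "intercept_mean": mean[:, 0],
        "slope_mean": mean[:, 1],
        "log_var_mean": mean[:, 2],
        "intercept_sd": np.sqrt(var[:, 0]),
        "slope_sd": np.sqrt(var[:, 1]),
        "log_var_sd": np.sqrt(var[:, 2]),
    })
    return PosteriorSummary(params=params, subject_effects=effects,
                            draws=pooled, n_chains=config.n_chains,
                            n_kept=len(pooled), acceptance=acc,
                            rhat_threshold=config.rhat_threshold)


def fit_variance_lmm(panel: pd.DataFrame, covariates: pd.DataFrame,
                     priors: PriorSpec | None = None,
                     config: MCMCConfig | None = None,
                     prior_only: bool = False) -> PosteriorSummary:
    """Fit the location-scale mixed model by Metropolis-within-Gibbs.

    Parameters
    ----------
    panel
        Long-format longitudinal data (subject_id, time, value).
    covariates
        One row per subject: subject_id plus covariate columns entering the
        mean model.
    priors, config
        Hyperparameters and chain settings; defaults follow the package's
        reference protocol (see :class:`~varisurv.mcmc.MCMCConfig`).
    prior_only
        Switch off the likelihood entirely (prior-predictive sampling, used
        for validation).

    Returns
    -------
    PosteriorSummary
        Parameter posterior table (mean/sd/2.5%/97.5%/R-hat), per-subject
        posterior means of (I_i, S_i, U_i), and the merged kept draws. A
        fit with any R-hat above the threshold is flagged (``converged``
        False), never silently accepted.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    stats = LongitudinalStats.from_panel(panel, covariates)
    cov_names = [c for c in covariates.columns if c != "subject_id"]
    return _run_chains(stats, priors, config, cov_names, prior_only=prior_only)
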