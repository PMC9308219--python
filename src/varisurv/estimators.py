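"""Two-stage and joint estimators of the variability effect.

Five ways to estimate the log-hazard coefficients (gamma1, gamma2, gamma3)
of a subject's latent intercept, slope, and log residual variance:

* ``fit_naive``  — per-subject OLS on all (or pre-cutoff) visits, then Cox;
* ``fit_lma``    — landmark analysis: OLS windows accumulated to each
  landmark, stacked into a landmark-stratified Cox with left truncation and
  a cluster-robust sandwich variance;
* ``fit_tdcox``  — the same accumulating summaries carried as time-varying
  covariates in a counting-process Cox;
* ``fit_rc``     — regression calibration: posterior means from the Bayesian
  location-scale mixed model as error-free covariates in a Cox model;
* ``fit_joint``  — the full shared-parameter joint model (no second stage).

The sample-based methods treat the stage-1 summaries as known, which is
what produces the attenuation this package exists to quantify.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxFit, fit_cox
from .simulate import SimulatedDataset
from .subject_ols import landmark_summaries, panel_summaries

SUMMARY_COLS = ["intercept", "slope", "log_var"]
GAMMA_NAMES = {"intercept": "gamma1", "slope": "gamma2", "log_var": "gamma3"}


@dataclass
class EstimatorResult:
    method: str
    coef: dict[str, float]
    se: dict[str, float]
    n_subjects: int
    n_excluded: int
    converged: bool
    flags: dict = field(default_factory=dict)
    cox_fit: CoxFit | None = None

    @property
    def gamma3(self) -> float:
        return self.coef["gamma3"]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coef": self.coef,
            "se": self.se,
            "n_subjects": self.n_subjects,
            "n_excluded": self.n_excluded,
            "converged": self.converged,
            "flags": {k: v for k, v in self.flags.items() if not k.startswith("_")},
        }


def _covariate_cols(dataset: SimulatedDataset) -> list[str]:
    return [c for c in dataset.covariates.columns if c != "subject_id"]


def _fit_cox_graceful(d: pd.DataFrame, covariates: list[str], **kwargs) -> CoxFit:
    """fit_cox, but summary columns without variation get coefficient 0.

    A cohort in which a stage-1 summary is identical for everyone carries
    no information about its effect; the estimate is 0 by construction
    rather than an error, and the dropped columns are recorded.
    """
    covariates = list(covariates)
    dropped = [c for c in covariates if c in SUMMARY_COLS
               and np.ptp(d[c].to_numpy(dtype=float)) == 0]
    fit = fit_cox(d, [c for c in covariates if c not in dropped], **kwargs)
    if dropped:
        names, coef = list(fit.names), list(fit.coef)
        k = len(coef)
        cov = np.zeros((k + len(dropped),) * 2)
        cov[:k, :k] = fit.cov
        fit.names = names + dropped
        fit.coef = np.asarray(coef + [0.0] * len(dropped))
        fit.cov = cov
        if fit.robust_cov is not None:
            rcov = np.zeros_like(cov)
            rcov[:k, :k] = fit.robust_cov
            fit.robust_cov = rcov
        fit.diagnostics["constant_covariates"] = dropped
    return fit


def _result_from_cox(method: str, fit: CoxFit, n_subjects: int,
                     n_excluded: int, robust: bool = False,
                     **flags) -> EstimatorResult:
    se = fit.robust_se if (robust and fit.robust_se is not None) else fit.se
    coef, ses = {}, {}
    for name, c, s in zip(fit.names, fit.coef, se):
        key = GAMMA_NAMES.get(name, name)
        coef[key] = float(c)
        ses[key] = float(s)
    return EstimatorResult(method=method, coef=coef, se=ses,
                           n_subjects=n_subjects, n_excluded=n_excluded,
                           converged=fit.converged, flags=flags, cox_fit=fit)


def fit_naive(dataset: SimulatedDataset,
              cutoff: float | None = None) -> EstimatorResult:
    """Per-subject OLS (optionally only data up to ``cutoff``) then Cox.

    ``cutoff=None`` uses every available visit (the classic naive method);
    ``cutoff=0`` is the no-future-information variant that uses lead-in
    data only. Subjects with fewer than three usable measurements are
    excluded and counted.
    """
    summaries = panel_summaries(dataset.panel, cutoff=cutoff)
    n_total = dataset.n_subjects
    cov_cols = _covariate_cols(dataset)
    d = (summaries.merge(dataset.survival, on="subject_id")
         .merge(dataset.covariates, on="subject_id"))
    if len(d) < 2:
        raise ValueError("fewer than 2 usable subjects")
    if d["event"].sum() == 0:
        raise ValueError("no events among usable subjects")
    d["stop"] = d["time"]
    fit = _fit_cox_graceful(d, cov_cols + SUMMARY_COLS)
    return _result_from_cox("naive", fit, n_subjects=len(d),
                            n_excluded=n_total - len(d), cutoff=cutoff)


def fit_lma(dataset: SimulatedDataset, landmarks=(0, 1, 2, 3, 4, 5),
            per_landmark: bool = False) -> EstimatorResult:
    """Stacked landmark analysis.

    For each landmark l: subjects still at risk (T_i > l) with >= 3
    measurements by l contribute one row with covariates from data up to l,
    entering the risk set at l (left truncation) in a stratum of their own.
    One stratified Cox fit over the stack gives the average effects across
    landmarks; the sandwich variance clusters on subject, since a subject
    appears in several strata.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    summaries = landmark_summaries(dataset.panel, landmarks,
                                   survival=dataset.survival)
    cov_cols = _covariate_cols(dataset)
    d = (summaries.merge(dataset.survival, on="subject_id")
         .merge(dataset.covariates, on="subject_id"))
    if d.empty:
        raise ValueError("no landmark has an eligible risk set")
    d["start"] = d["cutoff"]
    d["stop"] = d["time"]
    fit = _fit_cox_graceful(d, cov_cols + SUMMARY_COLS, strata_col="cutoff",
                            cluster_col="subject_id")
    res = _result_from_cox("lma", fit, n_subjects=d["subject_id"].nunique(),
                           n_excluded=dataset.n_subjects - d["subject_id"].nunique(),
                           robust=True, landmarks=list(map(float, landmarks)))
    if per_landmark:
        per = {}
        for lm in np.unique(landmarks):
            sub = d[d["cutoff"] == lm]
            if sub["event"].sum() == 0:
                continue
            try:
                f = fit_cox(sub, cov_cols + SUMMARY_COLS)
                per[float(lm)] = dict(zip(f.names, map(float, f.coef)))
            except ValueError:
                continue
        res.flags["per_landmark"] = per
    return res


def tdcox_rows(dataset: SimulatedDataset,
               update_times=(0, 1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Counting-process rows with summaries updated at each grid time.

    A subject's row over (u_l, min(u_{l+1}, T_i)] carries the OLS summary
    from data up to u_l; subjects enter once they have 3 measurements.
    """
    update_times = np.asarray(update_times, dtype=float)
    if np.any(np.diff(update_times) <= 0):
        raise ValueError("update_times must be strictly increasing")
    summaries = landmark_summaries(dataset.panel, update_times)
    d = summaries.merge(dataset.survival, on="subject_id")
    nxt = dict(zip(update_times[:-1], update_times[1:]))
    d["start"] = d["cutoff"]
    d["stop"] = np.minimum(d["cutoff"].map(nxt).fillna(np.inf), d["time"])
    d = d[d["stop"] > d["start"]]
    d["event"] = ((d["event"] == 1) & np.isclose(d["stop"], d["time"])).astype(int)
    return d.merge(dataset.covariates, on="subject_id")


def fit_tdcox(dataset: SimulatedDataset,
              update_times=(0, 1, 2, 3, 4, 5)) -> EstimatorResult:
    """Cox model with the OLS summaries as time-varying covariates."""
    d = tdcox_rows(dataset, update_times)
    cov_cols = _covariate_cols(dataset)
    fit = _fit_cox_graceful(d, cov_cols + SUMMARY_COLS)
    n_used = d["subject_id"].nunique()
    return _result_from_cox("tdcox", fit, n_subjects=n_used,
                            n_excluded=dataset.n_subjects - n_used,
                            update_times=list(map(float, update_times)))


def fit_rc(dataset: SimulatedDataset, priors=None, mcmc_config=None,
           return_posterior: bool = False) -> EstimatorResult:
    """Regression calibration: Bayesian mixed-model posterior means, then Cox.

    Stage 1 borrows strength across subjects, so no minimum-measurement
    rule applies and no subject is excluded.
    """
    from .mcmc import MCMCConfig, PriorSpec
    from .variance_lmm import fit_variance_lmm

    priors = priors or PriorSpec()
    mcmc_config = mcmc_config or MCMCConfig()
    post = fit_variance_lmm(dataset.panel, dataset.covariates,
                            priors=priors, config=mcmc_config)
    eff = post.subject_effects.rename(columns={
        "intercept_mean": "intercept", "slope_mean": "slope",
        "log_var_mean": "log_var"})
    cov_cols = _covariate_cols(dataset)
    d = (eff.merge(dataset.survival, on="subject_id")
         .merge(dataset.covariates, on="subject_id"))
    d["stop"] = d["time"]
    fit = _fit_cox_graceful(d, cov_cols + SUMMARY_COLS)
    res = _result_from_cox("rc", fit, n_subjects=len(d), n_excluded=0,
                           mcmc_converged=post.converged,
                           max_rhat=post.max_rhat)
    if not post.converged:
        res.flags["mcmc_warning"] = "stage-1 MCMC R-hat above threshold"
    if return_posterior:
        res.flags["_posterior"] = post
    return res


def fit_joint(dataset: SimulatedDataset, spec=None, priors=None,
              mcmc_config=None, return_posterior: bool = False) -> EstimatorResult:
    """Full Bayesian shared-parameter joint model."""
    from .joint_model import JointModelSpec, fit_joint as _fit_joint
    from .mcmc import MCMCConfig, PriorSpec

    spec = spec or JointModelSpec()
    priors = priors or PriorSpec()
    mcmc_config = mcmc_config or MCMCConfig()
    post = _fit_joint(dataset.panel, dataset.survival, dataset.covariates,
                      spec=spec, priors=priors, config=mcmc_config)
    params = post.params
    cov_cols = _covariate_cols(dataset)
    wanted = ([f"alpha_{c}" for c in cov_cols]
              + ["gamma1", "gamma2", "gamma3"])
    coef = {k.replace("alpha_x0", "x0"): float(params.loc[k, "mean"])
            for k in wanted if k in params.index}
    se = {k.replace("alpha_x0", "x0"): float(params.loc[k, "sd"])
          for k in wanted if k in params.index}
    res = EstimatorResult(method="joint", coef=coef, se=se,
                          n_subjects=dataset.n_subjects, n_excluded=0,
                          converged=post.converged,
                          flags={"max_rhat": post.max_rhat})
    if return_posterior:
        res.flags["_posterior"] = post
    return res


ESTIMATORS = {
    "naive": fit_naive,
    "lma": fit_lma,
    "tdcox": fit_tdcox,
    "rc": fit_rc,
    "joint": fit_joint,
}
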