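"""Cox proportional-hazards engine on counting-process data.

Newton-Raphson maximization of the stratified partial likelihood over
(start, stop] risk sets, with Efron or Breslow tie handling and a
cluster-robust sandwich variance built from score residuals. This is the
shared second stage for the naive, landmark, and time-dependent two-stage
estimators; left truncation (a landmark's delayed entry) is expressed
directly through the start column.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class CoxError(ValueError):
    pass


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_events: int
    n_rows: int
    ties: str
    robust_cov: np.ndarray | None = None
    n_clusters: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def robust_se(self) -> np.ndarray | None:
        if self.robust_cov is None:
            return None
        return np.sqrt(np.diag(self.robust_cov))

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.coef, "se": self.se}, index=self.names)
        if self.robust_cov is not None:
            out["robust_se"] = self.robust_se
        return out

    def to_dict(self) -> dict:
        d = {
            "coef": dict(zip(self.names, map(float, self.coef))),
            "se": dict(zip(self.names, map(float, self.se))),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_events": self.n_events,
            "ties": self.ties,
        }
        if self.robust_cov is not None:
            d["robust_se"] = dict(zip(self.names, map(float, self.robust_se)))
        return d


def _stratum_arrays(df, covariates, start_col, stop_col, event_col):
    start = df[start_col].to_numpy(dtype=float) if start_col in df else np.zeros(len(df))
    stop = df[stop_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    x = df[list(covariates)].to_numpy(dtype=float)
    if np.any(start >= stop):
        raise CoxError("every row must satisfy start < stop")
    if not np.all(np.isfinite(x)):
        raise CoxError("covariates must be finite")
    return start, stop, event, x


class _Stratum:
    """Pre-sorted arrays and risk-set machinery for one stratum."""

    def __init__(self, start, stop, event, x):
        self.start, self.stop, self.event, self.x = start, stop, event, x
        self.n, self.p = x.shape
        self.order_stop = np.argsort(stop, kind="stable")
        self.order_start = np.argsort(start, kind="stable")
        self.sorted_stop = stop[self.order_stop]
        self.sorted_start = start[self.order_start]
        ev_times = stop[event == 1]
        self.event_times, self.event_counts = np.unique(ev_times, return_counts=True)
        # tied-set membership per unique event time
        self.tied_rows = [np.flatnonzero((stop == t) & (event == 1))
                          for t in self.event_times]

    def risk_sums(self, r):
        """S0, S1, S2 over the risk set {start < t <= stop} per event time."""
        p = self.p
        rx = r[:, None] * self.x
        rxx = rx[:, :, None] * self.x[:, None, :]

        def suffix(arr, order, sorted_times):
            a = arr[order]
            cs = np.concatenate([np.cumsum(a[::-1], axis=0)[::-1],
                                 np.zeros((1,) + a.shape[1:])])
            idx = np.searchsorted(sorted_times, self.event_times, side="left")
            return cs[idx]

        s0 = (suffix(r[:, None], self.order_stop, self.sorted_stop)
              - suffix(r[:, None], self.order_start, self.sorted_start))[:, 0]
        s1 = (suffix(rx, self.order_stop, self.sorted_stop)
              - suffix(rx, self.order_start, self.sorted_start))
        s2 = (suffix(rxx, self.order_stop, self.sorted_stop)
              - suffix(rxx, self.order_start, self.sorted_start))
        return s0, s1, s2

    def loglik_grad_hess(self, beta, ties):
        eta = self.x @ beta
        r = np.exp(eta)
        s0, s1, s2 = self.risk_sums(r)
        ll = 0.0
        grad = np.zeros(self.p)
        hess = np.zeros((self.p, self.p))
        no_ties = np.all(self.event_counts == 1)
        if no_ties:
            rows = np.concatenate(self.tied_rows) if self.tied_rows else np.array([], int)
            ll = float(eta[rows].sum() - np.log(s0).sum())
            xbar = s1 / s0[:, None]
            grad = self.x[rows].sum(axis=0) - xbar.sum(axis=0)
            hess = -(np.einsum("e,eij->ij", 1.0 / s0, s2)
                     - np.einsum("ei,ej->ij", xbar, xbar))
            return ll, grad, hess
        for k, t in enumerate(self.event_times):
            rows = self.tied_rows[k]
            d = self.event_counts[k]
            s0d = r[rows].sum()
            s1d = (r[rows, None] * self.x[rows]).sum(axis=0)
            s2d = np.einsum("j,ji,jk->ik", r[rows], self.x[rows], self.x[rows])
            ll += float(eta[rows].sum())
            grad += self.x[rows].sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                den = s0[k] - frac * s0d
                num1 = s1[k] - frac * s1d
                num2 = s2[k] - frac * s2d
                xbar = num1 / den
                ll -= np.log(den)
                grad -= xbar
                hess -= num2 / den - np.outer(xbar, xbar)
        return ll, grad, hess

    def score_residuals(self, beta, ties):
        """Per-row score residuals (martingale-transform decomposition).

        Sub-step construction: at an event time with d tied events, each of
        the d sub-steps l carries hazard increment 1/S0_l over the risk set
        (tied subjects down-weighted by 1 - l/d under Efron), and each tied
        subject receives event share 1/d at every sub-step. The residuals
        sum exactly to the score vector.
        """
        r = np.exp(self.x @ beta)
        resid = np.zeros((self.n, self.p))
        for k, t in enumerate(self.event_times):
            at_risk = (self.start < t) & (self.stop >= t)
            rows = self.tied_rows[k]
            d = self.event_counts[k]
            in_d = np.zeros(self.n)
            in_d[rows] = 1.0
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                w = np.where(at_risk, 1.0 - frac * in_d, 0.0)
                s0 = float(w @ r)
                xbar = (w * r) @ self.x / s0
                dev = self.x - xbar
                resid += ((in_d / d - w * r / s0)[:, None]) * dev
        return resid


def _build_strata(df, covariates, start_col, stop_col, event_col, strata_col):
    if strata_col is None:
        groups = [(None, df)]
    else:
        groups = list(df.groupby(strata_col, sort=True))
    out = []
    for _, g in groups:
        out.append((_Stratum(*_stratum_arrays(g, covariates, start_col,
                                              stop_col, event_col)), g.index))
    return out


def fit_cox(df: pd.DataFrame, covariates, start_col: str = "start",
            stop_col: str = "stop", event_col: str = "event",
            strata_col: str | None = None, cluster_col: str | None = None,
            ties: str = "efron", max_iter: int = 50, tol: float = 1e-9,
            grad_tol: float = 1e-6) -> CoxFit:
    """Fit a (stratified) Cox model on counting-process rows.

    Newton-Raphson with step-halving; convergence when the relative change
    in log partial likelihood falls below ``tol`` or the gradient max-norm
    below ``grad_tol``. When ``cluster_col`` is given the cluster-robust
    sandwich covariance is attached to the fit.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = df.reset_index(drop=True)
    covariates = list(covariates)
    p = len(covariates)
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise CoxError("no events in the data")
    xs = df[covariates].to_numpy(dtype=float)
    const = np.std(xs, axis=0) == 0
    if np.any(const):
        raise CoxError(f"constant covariate(s): "
                       f"{[c for c, m in zip(covariates, const) if m]}")
    strata = _build_strata(df, covariates, start_col, stop_col, event_col,
                           strata_col)

    def objective(beta):
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for s, _ in strata:
            if s.event_times.size == 0:
                continue
            a, b, c = s.loglik_grad_hess(beta, ties)
            ll += a
            grad += b
            hess += c
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError("singular information matrix") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = objective(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = objective(new_beta)
            halvings += 1
        beta, grad, hess = new_beta, new_grad, new_hess
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        if rel_change < tol or np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    diagnostics = {}
    if np.max(np.abs(beta)) > 20:
        converged = False
        diagnostics["monotone_likelihood"] = (
            "a coefficient diverged; a covariate may perfectly separate events")
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise CoxError("singular information matrix at the optimum") from exc
    fit = CoxFit(names=covariates, coef=beta, cov=cov, loglik=float(ll),
                 n_iter=it, converged=converged, n_events=n_events,
                 n_rows=len(df), ties=ties, diagnostics=diagnostics)
    fit.diagnostics["_strata"] = strata  # cached for robust_sandwich
    if cluster_col is not None:
        robust_sandwich(fit, df, cluster_col=cluster_col)
    return fit


def robust_sandwich(fit: CoxFit, df: pd.DataFrame,
                    cluster_col: str) -> np.ndarray:
    """Cluster-robust covariance A^-1 B A^-1.

    A is the observed information at the fit; B the outer-product sum of
    cluster-summed score residuals. Stores the result on ``fit`` and
    returns it.
    """
    strata = fit.diagnostics.get("_strata")
    if strata is None:
        raise ValueError("fit does not carry cached strata; refit with fit_cox")
    df = df.reset_index(drop=True)
    p = len(fit.names)
    resid = np.zeros((len(df), p))
    pos = pd.Series(np.arange(len(df)), index=df.index)
    for s, idx in strata:
        if s.event_times.size:
            resid[pos[idx].to_numpy()] = s.score_residuals(fit.coef, fit.ties)
    clusters, cidx = np.unique(df[cluster_col].to_numpy(), return_inverse=True)
    if clusters.size < p:
        log.warning("fewer clusters (%d) than covariates (%d): robust "
                    "variance may be unstable", clusters.size, p)
    csum = np.zeros((clusters.size, p))
    np.add.at(csum, cidx, resid)
    b = csum.T @ csum
    a_inv = fit.cov
    fit.robust_cov = a_inv @ b @ a_inv
    fit.n_clusters = int(clusters.size)
    return fit.robust_cov


def partial_loglik(df: pd.DataFrame, covariates, beta,
                   ties: str = "efron", **cols) -> float:
    """Log partial likelihood at a fixed coefficient vector."""
    strata = _build_strata(df, list(covariates), cols.get("start_col", "start"),
                           cols.get("stop_col", "stop"),
                           cols.get("event_col", "event"),
                           cols.get("strata_col"))
    beta = np.asarray(beta, dtype=float)
    return float(sum(s.loglik_grad_hess(beta, ties)[0]
                     for s, _ in strata if s.event_times.size))
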