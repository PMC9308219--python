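"""Metropolis-within-Gibbs core shared by the mixed-model and joint fits.

The longitudinal likelihood reduces to per-subject sufficient statistics
(n, St, Stt, Sy, Sty, Syy), so every update is O(N) vectorized:

* fixed effects  — conjugate multivariate normal given effects + variances;
* (I_i, S_i)     — exact conjugate bivariate normal given U_i (mixed model);
  in the joint fit the same conditional serves as an independence proposal
  accepted on the survival-likelihood ratio;
* U_i, mu_v      — adaptive random-walk Metropolis (the log-variance enters
  the likelihood non-conjugately), plus a joint translation move
  (mu_v + d, U_i - d) that breaks their posterior correlation;
* Sigma          — conjugate inverse-Wishart;
* hazard heights — conjugate gamma via the interval-exposure (Poisson) form;
* (alpha, gamma) — adaptive-covariance random-walk Metropolis.

Proposal scales adapt during burn-in (Robbins-Monro toward standard target
acceptance rates) and are frozen afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .mcmc import MCMCConfig, PriorSpec

_EXP_CLIP = 50.0


def _exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


@dataclass
class LongitudinalStats:
    """Per-subject sufficient statistics of the longitudinal panel."""

    subject_ids: np.ndarray
    n: np.ndarray
    st: np.ndarray
    stt: np.ndarray
    sy: np.ndarray
    sty: np.ndarray
    syy: np.ndarray
    x: np.ndarray  # (N, q) baseline covariates of the longitudinal model

    @property
    def n_subjects(self) -> int:
        return self.n.size

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, covariates: pd.DataFrame
                   ) -> "LongitudinalStats":
        cov = covariates.sort_values("subject_id").reset_index(drop=True)
        ids = cov["subject_id"].to_numpy()
        lookup = {s: i for i, s in enumerate(ids)}
        if panel.empty:
            raise ValueError("empty longitudinal panel")
        sid = panel["subject_id"].map(lookup).to_numpy()
        if np.any(pd.isna(sid)):
            raise ValueError("panel contains subjects missing from covariates")
        sid = sid.astype(int)
        t = panel["time"].to_numpy(dtype=float)
        y = panel["value"].to_numpy(dtype=float)
        k = ids.size
        xcols = [c for c in cov.columns if c != "subject_id"]
        return cls(
            subject_ids=ids,
            n=np.bincount(sid, minlength=k).astype(float),
            st=np.bincount(sid, weights=t, minlength=k),
            stt=np.bincount(sid, weights=t * t, minlength=k),
            sy=np.bincount(sid, weights=y, minlength=k),
            sty=np.bincount(sid, weights=t * y, minlength=k),
            syy=np.bincount(sid, weights=y * y, minlength=k),
            x=cov[xcols].to_numpy(dtype=float),
        )


@dataclass
class SurvivalStats:
    """Interval-exposure form of the survival data for the Poisson likelihood."""

    exposure: np.ndarray       # (N, K) time spent in each hazard interval
    event: np.ndarray          # (N,) event indicator
    event_interval: np.ndarray  # (N,) index of interval containing T (or -1)
    z: np.ndarray              # (N, q2) survival covariates

    @property
    def n_intervals(self) -> int:
        return self.exposure.shape[1]

    @property
    def events_per_interval(self) -> np.ndarray:
        k = self.n_intervals
        idx = self.event_interval[self.event == 1]
        return np.bincount(idx, minlength=k).astype(float)


class GibbsSampler:
    """One chain of the location-scale (joint) model sampler."""

    def __init__(self, stats: LongitudinalStats, priors: PriorSpec,
                 rng: np.random.Generator,
                 survival: SurvivalStats | None = None,
                 active_gamma=(True, True, True),
                 prior_only: bool = False):
        self.s = stats
        self.priors = priors
        self.rng = rng
        self.surv = survival
        self.active_gamma = np.asarray(active_gamma, dtype=bool)
        self.prior_only = prior_only
        self.N = stats.n_subjects
        self.q = stats.x.shape[1]
        self.kfix = 2 + self.q
        # per-subject fixed-effect design cross-product blocks (W^T W)_i
        n, st, stt, x = stats.n, stats.st, stats.stt, stats.x
        ww = np.zeros((self.N, self.kfix, self.kfix))
        ww[:, 0, 0] = n
        ww[:, 0, 1] = ww[:, 1, 0] = st
        ww[:, 1, 1] = stt
        for j in range(self.q):
            ww[:, 0, 2 + j] = ww[:, 2 + j, 0] = n * x[:, j]
            ww[:, 1, 2 + j] = ww[:, 2 + j, 1] = st * x[:, j]
            for l in range(self.q):
                ww[:, 2 + j, 2 + l] = n * x[:, j] * x[:, l]
        self.ww = ww
        self.g11, self.g12, self.g22 = n, st, stt  # (I,S) information blocks
        if survival is not None:
            self.q2 = survival.z.shape[1]
            self.n_ag = self.q2 + int(self.active_gamma.sum())
        self._init_state()
        self._init_adaptation()

    # ---------------------------------------------------------------- state
    def _init_state(self):
        """Overdispersed starting values from crude (pooled + per-subject) OLS."""
        s, rng = self.s, self.rng
        wy = np.zeros(self.kfix)
        wy[0] = np.sum(s.sy)
        wy[1] = np.sum(s.sty)
        for j in range(self.q):
            wy[2 + j] = np.sum(s.x[:, j] * s.sy)
        pooled = self.ww.sum(axis=0) + 1e-8 * np.eye(self.kfix)
        b = np.linalg.solve(pooled, wy)
        # per-subject OLS (where estimable) for crude latent effects
        sxx = s.stt - s.st ** 2 / np.maximum(s.n, 1.0)
        sxy = s.sty - s.st * s.sy / np.maximum(s.n, 1.0)
        ok = (s.n >= 3) & (sxx > 1e-10)
        slope = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        interc = s.sy / np.maximum(s.n, 1.0) - slope * s.st / np.maximum(s.n, 1.0)
        rss = np.maximum(
            s.syy - 2 * interc * s.sy - 2 * slope * s.sty
            + 2 * interc * slope * s.st + interc ** 2 * s.n
            + slope ** 2 * s.stt, 1e-8)
        logv = np.where(ok, np.log(rss / np.maximum(s.n - 2, 1.0)), np.nan)
        mu0 = float(np.nanmedian(logv)) if np.any(ok) else 0.0
        eff = np.zeros((self.N, 3))
        eff[:, 0] = np.where(ok, np.clip(interc - b[0] - s.x @ b[2:], -12, 12), 0.0)
        eff[:, 1] = np.where(ok, np.clip(slope - b[1], -4, 4), 0.0)
        eff[:, 2] = np.where(ok, np.clip(logv - mu0, -4, 4), 0.0)
        cov = np.cov(eff.T) if self.N > 3 else np.eye(3)
        cov = 0.9 * cov + 0.1 * np.diag(np.maximum(np.diag(cov), 0.05))
        # overdisperse across chains
        self.b = b + 0.2 * rng.standard_normal(self.kfix)
        self.mu = mu0 + 0.4 * rng.standard_normal()
        self.effects = eff
        self.sigma = cov + 1e-3 * np.eye(3)
        if self.surv is not None:
            total_exposure = float(self.surv.exposure.sum())
            rate = max(self.surv.event.sum() / max(total_exposure, 1e-9), 1e-4)
            self.lam = np.full(self.surv.n_intervals,
                               rate * _exp(0.3 * rng.standard_normal()))
            self.ag = 0.1 * rng.standard_normal(self.n_ag)

    def _init_adaptation(self):
        self.step_u = np.full(self.N, 1.0)
        self.step_mu = 0.1
        self.step_shift = 0.1
        self.acc = {"u": 0.0, "mu": 0.0, "shift": 0.0, "is": 1.0, "ag": 0.0}
        self._acc_n = {k: 0 for k in self.acc}
        if self.surv is not None:
            self.step_ag = 0.1
            self._ag_mean = np.zeros(self.n_ag)
            self._ag_cov = np.eye(self.n_ag) * 1e-4
            self._ag_count = 0

    # ------------------------------------------------------------- helpers
    @property
    def gamma_full(self) -> np.ndarray:
        g = np.zeros(3)
        if self.surv is not None:
            g[self.active_gamma] = self.ag[self.q2:]
        return g

    def _eta(self, effects=None) -> np.ndarray:
        effects = self.effects if effects is None else effects
        return self.surv.z @ self.ag[:self.q2] + effects @ self.gamma_full

    def _cum_hazard(self) -> np.ndarray:
        return self.surv.exposure @ self.lam

    def _surv_loglik_subject(self, eta, cumhaz) -> np.ndarray:
        return self.surv.event * eta - _exp(eta) * cumhaz

    def _fixed_intercepts(self) -> np.ndarray:
        return self.b[0] + self.s.x @ self.b[2:]

    def _sse(self, intercept_dev=None, slope_dev=None) -> np.ndarray:
        """Per-subject residual sum of squares around the full mean."""
        s = self.s
        a = self._fixed_intercepts() + (self.effects[:, 0] if intercept_dev
                                        is None else intercept_dev)
        c = self.b[1] + (self.effects[:, 1] if slope_dev is None else slope_dev)
        return (s.syy - 2 * a * s.sy - 2 * c * s.sty + 2 * a * c * s.st
                + a * a * s.n + c * c * s.stt)

    def _tau(self) -> np.ndarray:
        """Per-subject residual precision exp(-(mu_v + U_i))."""
        if self.prior_only:
            return np.zeros(self.N)
        return _exp(-(self.mu + self.effects[:, 2]))

    def _adapt(self, key, scale_attr, accepted, it, target):
        self._acc_n[key] += 1
        self.acc[key] += (np.mean(accepted) - self.acc[key]) / self._acc_n[key]
        if it < self.n_adapt:
            rate = min(0.25, 2.0 / np.sqrt(it + 10.0))
            delta = rate * (np.asarray(accepted, dtype=float) - target)
            cur = getattr(self, scale_attr)
            setattr(self, scale_attr, cur * np.exp(delta))

    # ------------------------------------------------------------- updates
    def _update_fixed_effects(self):
        s = self.s
        tau = self._tau()
        prec = np.einsum("i,ikl->kl", tau, self.ww) \
            + np.eye(self.kfix) / self.priors.fixed_effect_var
        i_dev, s_dev = self.effects[:, 0], self.effects[:, 1]
        sr = s.sy - i_dev * s.n - s_dev * s.st
        str_ = s.sty - i_dev * s.st - s_dev * s.stt
        h = np.zeros(self.kfix)
        h[0] = np.sum(tau * sr)
        h[1] = np.sum(tau * str_)
        for j in range(self.q):
            h[2 + j] = np.sum(tau * s.x[:, j] * sr)
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, h)
        z = self.rng.standard_normal(self.kfix)
        self.b = mean + np.linalg.solve(chol.T, z)

    def _intercept_slope_conditional(self):
        """Posterior (mixed model) conditional of (I_i, S_i) given U_i."""
        s = self.s
        tau = self._tau()
        omega = np.linalg.inv(self.sigma)
        u = self.effects[:, 2]
        # prior conditional precision = omega[:2,:2]; linear term -omega[:2,2]*u
        p11 = tau * self.g11 + omega[0, 0]
        p12 = tau * self.g12 + omega[0, 1]
        p22 = tau * self.g22 + omega[1, 1]
        a0 = self._fixed_intercepts()
        sr = s.sy - a0 * s.n - self.b[1] * s.st
        str_ = s.sty - a0 * s.st - self.b[1] * s.stt
        h1 = tau * sr - omega[0, 2] * u
        h2 = tau * str_ - omega[1, 2] * u
        det = p11 * p22 - p12 * p12
        m1 = (p22 * h1 - p12 * h2) / det
        m2 = (p11 * h2 - p12 * h1) / det
        return m1, m2, p11, p12, p22

    def _sample_bvn(self, m1, m2, p11, p12, p22):
        """Draw from N((m1,m2), P^-1) for vectors of 2x2 precisions."""
        l11 = np.sqrt(p11)
        l21 = p12 / l11
        l22 = np.sqrt(p22 - l21 * l21)
        z1 = self.rng.standard_normal(self.N)
        z2 = self.rng.standard_normal(self.N)
        e2 = z2 / l22
        e1 = (z1 - l21 * e2) / l11
        return m1 + e1, m2 + e2

    def _update_intercept_slope(self, it):
        m1, m2, p11, p12, p22 = self._intercept_slope_conditional()
        new1, new2 = self._sample_bvn(m1, m2, p11, p12, p22)
        if self.surv is None:
            self.effects[:, 0] = new1
            self.effects[:, 1] = new2
            return
        # joint fit: exact longitudinal conditional is an independence
        # proposal; accept on the survival likelihood ratio
        cumhaz = self._cum_hazard()
        eta_old = self._eta()
        prop = self.effects.copy()
        prop[:, 0], prop[:, 1] = new1, new2
        eta_new = self._eta(prop)
        log_r = (self._surv_loglik_subject(eta_new, cumhaz)
                 - self._surv_loglik_subject(eta_old, cumhaz))
        accept = np.log(self.rng.uniform(size=self.N)) < log_r
        self.effects[accept, 0] = new1[accept]
        self.effects[accept, 1] = new2[accept]
        self.acc["is"] += (np.mean(accept) - self.acc["is"]) / (it + 1)

    def _log_target_u(self, u, sse, omega):
        # conditional prior of U given (I, S)
        m_cond = -(omega[0, 2] * self.effects[:, 0]
                   + omega[1, 2] * self.effects[:, 1]) / omega[2, 2]
        lp = -0.5 * omega[2, 2] * (u - m_cond) ** 2
        if not self.prior_only:
            lp = lp - 0.5 * self.s.n * (self.mu + u) \
                - 0.5 * _exp(-(self.mu + u)) * sse
        return lp

    def _update_u(self, it):
        omega = np.linalg.inv(self.sigma)
        sse = self._sse()
        u = self.effects[:, 2]
        prop = u + self.step_u * self.rng.standard_normal(self.N)
        log_r = self._log_target_u(prop, sse, omega) \
            - self._log_target_u(u, sse, omega)
        if self.surv is not None:
            g3 = self.gamma_full[2]
            cumhaz = self._cum_hazard()
            eta = self._eta()
            eta_prop = eta + g3 * (prop - u)
            log_r += (self._surv_loglik_subject(eta_prop, cumhaz)
                      - self._surv_loglik_subject(eta, cumhaz))
        accept = np.log(self.rng.uniform(size=self.N)) < log_r
        self.effects[accept, 2] = prop[accept]
        self._adapt("u", "step_u", accept, it, target=0.44)

    def _loglik_mu(self, mu, sse):
        if self.prior_only:
            ll = 0.0
        else:
            ll = np.sum(-0.5 * self.s.n * (mu + self.effects[:, 2])
                        - 0.5 * _exp(-(mu + self.effects[:, 2])) * sse)
        return ll - 0.5 * mu * mu / self.priors.fixed_effect_var

    def _update_mu(self, it):
        sse = self._sse()
        prop = self.mu + self.step_mu * self.rng.standard_normal()
        log_r = self._loglik_mu(prop, sse) - self._loglik_mu(self.mu, sse)
        accept = np.log(self.rng.uniform()) < log_r
        if accept:
            self.mu = prop
        self._adapt("mu", "step_mu", accept, it, target=0.44)
        # translation move: (mu + d, U - d) leaves the longitudinal
        # likelihood invariant; the prior of the triples and the survival
        # term decide acceptance
        d = self.step_shift * self.rng.standard_normal()
        omega = np.linalg.inv(self.sigma)
        u = self.effects[:, 2]
        su = np.sum(u)
        cross = np.sum(omega[0, 2] * self.effects[:, 0]
                       + omega[1, 2] * self.effects[:, 1])
        log_r = -0.5 * omega[2, 2] * (-2 * d * su + self.N * d * d) \
            + d * cross \
            - 0.5 * ((self.mu + d) ** 2 - self.mu ** 2) / self.priors.fixed_effect_var
        if self.surv is not None:
            g3 = self.gamma_full[2]
            cumhaz = self._cum_hazard()
            eta = self._eta()
            log_r += np.sum(self._surv_loglik_subject(eta - g3 * d, cumhaz)
                            - self._surv_loglik_subject(eta, cumhaz))
        accept = np.log(self.rng.uniform()) < log_r
        if accept:
            self.mu += d
            self.effects[:, 2] -= d
        self._adapt("shift", "step_shift", accept, it, target=0.44)

    def _update_sigma(self):
        # conditional on the latent triples even in prior-only mode: the
        # Gibbs pair (Sigma, effects) then targets the joint prior exactly
        scale = self.priors.iw_scale * np.eye(3) + self.effects.T @ self.effects
        df = self.priors.iw_df + self.N
        self.sigma = invwishart.rvs(df=df, scale=scale, random_state=self.rng)

    def _update_hazard(self):
        sv = self.surv
        expeta = _exp(self._eta())
        rate = self.priors.hazard_rate + sv.exposure.T @ expeta
        shape = self.priors.hazard_shape + sv.events_per_interval
        self.lam = self.rng.gamma(shape, 1.0 / rate)

    def _surv_loglik_total(self, ag) -> float:
        sv = self.surv
        g = np.zeros(3)
        g[self.active_gamma] = ag[self.q2:]
        eta = sv.z @ ag[:self.q2] + self.effects @ g
        cumhaz = self._cum_hazard()
        return float(np.sum(sv.event * eta - _exp(eta) * cumhaz)
                     - 0.5 * np.sum(ag * ag) / self.priors.fixed_effect_var)

    def _update_ag(self, it, n_steps: int = 8):
        # the hazard-coefficient block is cheap to evaluate, so several MH
        # sub-steps per scan buy mixing for the weakly identified gammas
        d = self.n_ag
        if self._ag_count >= 100:
            cov = self._ag_cov + 1e-10 * np.eye(d)
        else:
            cov = 1e-3 * np.eye(d)
        chol = np.linalg.cholesky((2.38 ** 2 / d) * cov)
        cur_ll = self._surv_loglik_total(self.ag)
        n_acc = 0
        for _ in range(n_steps):
            prop = self.ag + self.step_ag * (chol @ self.rng.standard_normal(d))
            prop_ll = self._surv_loglik_total(prop)
            if np.log(self.rng.uniform()) < prop_ll - cur_ll:
                self.ag, cur_ll = prop, prop_ll
                n_acc += 1
        self._adapt("ag", "step_ag", n_acc / n_steps, it, target=0.234)
        if it < self.n_adapt:
            self._ag_count += 1
            c = self._ag_count
            delta = self.ag - self._ag_mean
            self._ag_mean += delta / c
            self._ag_cov += (np.outer(delta, self.ag - self._ag_mean)
                             - self._ag_cov) / c

    # ----------------------------------------------------------------- run
    def run(self, config: MCMCConfig, param_names, collect_effects=True):
        self.n_adapt = config.adapt_iters
        n_total = config.n_burn + config.n_keep
        kept = []
        eff_sum = np.zeros((self.N, 3))
        eff_sumsq = np.zeros((self.N, 3))
        n_eff = 0
        for it in range(n_total):
            self._update_fixed_effects()
            self._update_intercept_slope(it)
            self._update_u(it)
            self._update_mu(it)
            self._update_sigma()
            if self.surv is not None:
                self._update_hazard()
                self._update_ag(it)
            if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
                kept.append(self._snapshot())
                if collect_effects:
                    eff_sum += self.effects
                    eff_sumsq += self.effects ** 2
                    n_eff += 1
        draws = pd.DataFrame(kept, columns=param_names)
        return draws, eff_sum, eff_sumsq, max(n_eff, 1)

    def _snapshot(self):
        sd = np.sqrt(np.diag(self.sigma))
        row = list(self.b) + [self.mu] + list(sd) + [
            self.sigma[0, 1] / (sd[0] * sd[1]),
            self.sigma[0, 2] / (sd[0] * sd[2]),
            self.sigma[1, 2] / (sd[1] * sd[2]),
        ]
        if self.surv is not None:
            row += list(self.ag) + list(self.lam)
        return row
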