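"""MCMC configuration, priors, convergence diagnostics, summaries.

The Bayesian fits in this package (the location-scale mixed model and the
full joint model) run several parallel Metropolis-within-Gibbs chains with
different starting values; convergence is monitored by the potential scale
reduction factor, and posterior means/SDs serve as estimates/SEs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MCMCConfig:
    """Chain lengths and seeds.

    The reference profile (15,000 burn-in + 15,000 kept draws, 3 chains)
    matches the package's full-scale simulation protocol; tests and the
    fast experiment profile use much shorter, flagged runs. Adaptation of
    proposal scales runs for ``n_adapt`` iterations (default: the whole
    burn-in — a long adaptation period helps the level-1 variance effects)
    and is frozen afterwards so the kept draws target the exact posterior.
    """

    n_chains: int = 3
    n_burn: int = 15000
    n_keep: int = 15000
    thin: int = 1
    seed: int = 0
    n_adapt: int | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 so R-hat is defined")
        if self.n_burn <= 0 or self.n_keep <= 0:
            raise ValueError("n_burn and n_keep must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def adapt_iters(self) -> int:
        return self.n_burn if self.n_adapt is None else self.n_adapt


def fast_config(seed: int = 0, n_chains: int = 2, n_burn: int = 600,
                n_keep: int = 600) -> MCMCConfig:
    """Shortened, flagged profile for tests and scaled-down experiments."""
    return MCMCConfig(n_chains=n_chains, n_burn=n_burn, n_keep=n_keep, seed=seed)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Fixed effects, hazard coefficients, and the mean log variance get
    N(0, ``fixed_effect_var``) priors; piecewise-hazard heights get
    Gamma(``hazard_shape``, rate=``hazard_rate``) (mean a/b); the
    random-effects covariance gets an inverse-Wishart with scale matrix
    ``iw_scale * I`` and ``iw_df`` degrees of freedom (default dimension+1,
    weakly informative).
    """

    fixed_effect_var: float = 100.0
    hazard_shape: float = 0.1
    hazard_rate: float = 1.0
    iw_scale: float = 0.01
    iw_df: float = 4.0

    def __post_init__(self) -> None:
        for name in ("fixed_effect_var", "hazard_shape", "hazard_rate", "iw_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iw_df <= 2:  # dimension 3: df must exceed p - 1
            raise ValueError("iw_df must exceed dimension - 1 = 2")


def gelman_rubin(chains, split: bool = True) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws). With ``split=True`` each chain is
    halved first, so within-chain drift also inflates the statistic. The
    classic PSRF sqrt(((n-1)/n W + B/n) / W) is clamped below at 1, so
    chains with zero between-chain variance report exactly 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if c.shape[1] < 4:
        raise ValueError("chains too short for a meaningful R-hat")
    if split:
        half = c.shape[1] // 2
        c = np.vstack([c[:, :half], c[:, half:2 * half]])
    m, n = c.shape
    means = c.mean(axis=1)
    w = float(np.mean(np.var(c, axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w == 0.0:
        return 1.0
    var_hat = (n - 1) / n * w + b_over_n
    return max(1.0, float(np.sqrt(var_hat / w)))


@dataclass
class PosteriorSummary:
    """Posterior summaries of a Bayesian fit.

    ``params`` is indexed by parameter name with columns mean, sd, q2.5,
    q97.5, rhat; ``subject_effects`` holds per-subject posterior means (and
    SDs) of the latent triples; ``draws`` retains the merged post-burn-in
    draws (kept x params) for downstream checks.
    """

    params: pd.DataFrame
    subject_effects: pd.DataFrame
    draws: pd.DataFrame
    n_chains: int
    n_kept: int
    acceptance: dict = field(default_factory=dict)
    rhat_threshold: float = 1.1

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.params["rhat"].to_numpy()))

    @property
    def converged(self) -> bool:
        return bool(self.max_rhat <= self.rhat_threshold)

    def credible_interval(self, name: str) -> tuple[float, float]:
        row = self.params.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(orient="index"),
            "n_chains": self.n_chains,
            "n_kept": self.n_kept,
            "max_rhat": self.max_rhat,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize_chains(chain_draws: list[pd.DataFrame],
                     rhat_threshold: float = 1.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-chain draw tables into a summary frame + pooled draws."""
    names = list(chain_draws[0].columns)
    pooled = pd.concat(chain_draws, ignore_index=True)
    rows = {}
    for name in names:
        stacked = np.vstack([d[name].to_numpy() for d in chain_draws])
        x = stacked.ravel()
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
            "rhat": gelman_rubin(stacked) if stacked.shape[1] >= 4 else np.nan,
        }
    return pd.DataFrame(rows).T[["mean", "sd", "q2.5", "q97.5", "rhat"]], pooled
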