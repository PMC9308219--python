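"""Stage-1 sample-based subject summaries.

Per-subject ordinary least squares of the biomarker on measurement time,
yielding the sample analogues of the latent triple: fitted intercept (I),
slope (S), and log residual variance (U). Optionally restricted to the data
accumulated up to a cutoff time, which is how landmark and time-dependent
second stages obtain their covariates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Residual-variance floor applied when a subject's fit is exactly collinear.
ZERO_RSS_EPS = 1e-10

#: Minimum number of measurements needed to estimate all three summaries.
MIN_MEASUREMENTS = 3


@dataclass(frozen=True)
class OLSSummary:
    subject_id: int
    cutoff_time: float | None
    n_obs: int
    intercept_hat: float
    slope_hat: float
    log_resid_var_hat: float
    degenerate: bool = False


class InsufficientMeasurementsError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


def ols_summary(times, values, cutoff: float | None = None,
                subject_id: int = 0) -> OLSSummary:
    """OLS of values on times for one subject.

    At least three measurements (after applying the cutoff) are required so
    that the residual variance is estimable; its log is floored at
    ``log(ZERO_RSS_EPS)`` when the points are exactly collinear, and the
    summary is flagged degenerate rather than dropped (dropping would couple
    inclusion to the outcome).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if cutoff is not None:
        keep = t <= cutoff + 1e-12
        t, y = t[keep], y[keep]
    m = t.size
    if m < MIN_MEASUREMENTS:
        raise InsufficientMeasurementsError(
            f"subject {subject_id}: {m} measurements < {MIN_MEASUREMENTS}")
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    if sxx <= 0:
        raise DegenerateDesignError(f"subject {subject_id}: all times identical")
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * tbar
    rss = float(np.sum((y - intercept - slope * t) ** 2))
    # sample variance of the residuals (divisor m-1): the residuals have
    # mean zero by construction, so this is var() as statistical software
    # computes it, not the unbiased OLS error-variance estimate RSS/(m-2)
    resid_var = rss / (m - 1)
    degenerate = resid_var <= ZERO_RSS_EPS
    log_var = float(np.log(max(resid_var, ZERO_RSS_EPS)))
    return OLSSummary(subject_id=subject_id, cutoff_time=cutoff, n_obs=m,
                      intercept_hat=float(intercept), slope_hat=slope,
                      log_resid_var_hat=log_var, degenerate=degenerate)


def panel_summaries(panel: pd.DataFrame, cutoff: float | None = None,
                    min_obs: int = MIN_MEASUREMENTS) -> pd.DataFrame:
    """Vectorized per-subject OLS summaries for a long-format panel.

    Subjects with fewer than ``min_obs`` usable measurements are omitted.
    Returns a tidy frame (subject_id, cutoff, n_obs, intercept, slope,
    log_var, degenerate).
    """
    t = panel["time"].to_numpy(dtype=float)
    y = panel["value"].to_numpy(dtype=float)
    sid_raw = panel["subject_id"].to_numpy()
    if cutoff is not None:
        keep = t <= cutoff + 1e-12
        t, y, sid_raw = t[keep], y[keep], sid_raw[keep]
    uniq, sid = np.unique(sid_raw, return_inverse=True)
    k = uniq.size
    n = np.bincount(sid, minlength=k).astype(float)
    ok = n >= min_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = np.bincount(sid, weights=t, minlength=k) / n
        ybar = np.bincount(sid, weights=y, minlength=k) / n
        dt = t - tbar[sid]
        dy = y - ybar[sid]
        sxx = np.bincount(sid, weights=dt * dt, minlength=k)
        sxy = np.bincount(sid, weights=dt * dy, minlength=k)
        slope = sxy / sxx
        intercept = ybar - slope * tbar
        resid = dy - slope[sid] * dt
        rss = np.bincount(sid, weights=resid * resid, minlength=k)
        resid_var = rss / (n - 1)  # sample variance of residuals

    ok &= sxx > 0
    degenerate = resid_var <= ZERO_RSS_EPS
    log_var = np.log(np.maximum(resid_var, ZERO_RSS_EPS))
    out = pd.DataFrame({
        "subject_id": uniq,
        "cutoff": np.nan if cutoff is None else cutoff,
        "n_obs": n.astype(int),
        "intercept": intercept,
        "slope": slope,
        "log_var": log_var,
        "degenerate": degenerate,
    })
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("panel_summaries: omitted %d subjects with <%d usable "
                 "measurements at cutoff %s", n_dropped, min_obs, cutoff)
    return out[ok].reset_index(drop=True)


def landmark_summaries(panel: pd.DataFrame, landmarks,
                       survival: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject OLS summaries at each landmark time.

    For landmark l the window is all measurements at times <= l; when a
    survival table is given, only subjects still at risk (T_i > l, strict)
    are retained — the risk-set condition of a landmark analysis.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.size == 0 or np.any(np.diff(landmarks) <= 0):
        raise ValueError("landmarks must be nonempty and strictly increasing")
    frames = []
    for lm in landmarks:
        s = panel_summaries(panel, cutoff=float(lm))
        if survival is not None:
            at_risk = survival.loc[survival["time"] > lm, "subject_id"]
            s = s[s["subject_id"].isin(at_risk)]
        if s.empty:
            log.warning("landmark %s: no eligible subjects", lm)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)
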