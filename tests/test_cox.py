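"""Cox engine against brute-force partial-likelihood oracles and lifelines."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from varisurv.cox import CoxError, fit_cox, partial_loglik, robust_sandwich


def brute_force_loglik(df, beta):
    """Hand-written Breslow/Efron-free (no ties) partial likelihood."""
    ll = 0.0
    eta = df["x"].to_numpy() * beta
    start = df.get("start", pd.Series(np.zeros(len(df)))).to_numpy()
    stop = df["stop"].to_numpy()
    for _, row in df[df["event"] == 1].iterrows():
        t = row["stop"]
        at_risk = (start < t) & (stop >= t)
        ll += row["x"] * beta - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


def brute_force_score_residuals(df, beta):
    """O(n^2) score residuals from first principles (no ties)."""
    n = len(df)
    x = df["x"].to_numpy()
    eta = x * beta
    start = df.get("start", pd.Series(np.zeros(n))).to_numpy()
    stop = df["stop"].to_numpy()
    event = df["event"].to_numpy()
    resid = np.zeros(n)
    for j in np.flatnonzero(event == 1):
        t = stop[j]
        at_risk = (start < t) & (stop >= t)
        s0 = np.sum(np.exp(eta[at_risk]))
        xbar = np.sum(np.exp(eta[at_risk]) * x[at_risk]) / s0
        for i in np.flatnonzero(at_risk):
            dn = 1.0 if i == j else 0.0
            resid[i] += (dn - np.exp(eta[i]) / s0) * (x[i] - xbar)
    return resid


@pytest.fixture
def toy_df():
    # six subjects, one covariate, no ties
    return pd.DataFrame({
        "stop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 0, 1, 1, 0, 1],
        "x": [0.5, -0.2, 1.1, 0.0, -0.8, 0.3],
    })


@pytest.fixture
def random_df():
    rng = np.random.default_rng(10)
    n = 120
    x = rng.standard_normal(n)
    d = rng.exponential(1.0) * np.exp(-0.7 * x) * rng.exponential(size=n)
    c = rng.uniform(0.1, 2.0, size=n)
    return pd.DataFrame({
        "stop": np.minimum(d, c),
        "event": (d <= c).astype(int),
        "x": x,
        "x2": rng.standard_normal(n),
    })


class TestFitCox:
    def test_matches_1d_brute_force_maximizer(self, toy_df):
        fit = fit_cox(toy_df, ["x"], tol=1e-12)
        opt = minimize_scalar(lambda b: -brute_force_loglik(toy_df, b),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(opt.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-opt.fun, abs=1e-8)
        assert fit.converged

    def test_symmetric_groups_give_zero_coefficient(self):
        # identical event patterns in both covariate groups
        df = pd.DataFrame({
            "stop": [1, 2, 3, 4] * 2,
            "event": [1, 0, 1, 0] * 2,
            "x": [0.0] * 4 + [1.0] * 4,
        })
        fit = fit_cox(df, ["x"])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_on_simulated_cohort(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.standard_normal(n)
        d = rng.exponential(size=n) / (0.2 * np.exp(0.5 * x))
        c = rng.uniform(1, 8, size=n)
        df = pd.DataFrame({"stop": np.minimum(d, c),
                           "event": (d <= c).astype(int), "x": x})
        fit = fit_cox(df, ["x"])
        assert abs(fit.coef[0] - 0.5) < 3 * fit.se[0]

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(6)
        n = 150
        df = pd.DataFrame({
            "stop": rng.integers(1, 12, size=n).astype(float),  # many ties
            "event": rng.integers(0, 2, size=n),
            "x": rng.standard_normal(n),
            "x2": (rng.uniform(size=n) > 0.5).astype(float),
        })
        fit = fit_cox(df, ["x", "x2"], ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(df.rename(columns={"stop": "t"}), duration_col="t",
                event_col="event")
        assert np.allclose(fit.coef, cph.params_.values, atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_no_events_or_constant_covariate_rejected(self, toy_df):
        dead = toy_df.assign(event=0)
        with pytest.raises(CoxError, match="no events"):
            fit_cox(dead, ["x"])
        with pytest.raises(CoxError, match="constant"):
            fit_cox(toy_df.assign(x=1.0), ["x"])

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly orders the events before all censorings
        df = pd.DataFrame({
            "stop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [3.0, 2.5, 2.0, -1.0, -1.5, -2.0],
        })
        fit = fit_cox(df, ["x"])
        assert not fit.converged
        assert "monotone_likelihood" in fit.diagnostics


class TestInvariances:
    def test_time_shift_leaves_fit_unchanged(self, random_df):
        fit = fit_cox(random_df, ["x", "x2"])
        shifted = random_df.assign(stop=random_df["stop"] + 100.0)
        fit2 = fit_cox(shifted, ["x", "x2"])
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-9)
        assert np.allclose(fit.coef, fit2.coef, atol=1e-9)

    def test_single_stratum_equals_unstratified(self, random_df):
        df = random_df.assign(g="all")
        fit = fit_cox(random_df, ["x", "x2"])
        fit2 = fit_cox(df, ["x", "x2"], strata_col="g")
        assert np.allclose(fit.coef, fit2.coef, atol=1e-12)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-12)

    def test_efron_equals_breslow_without_ties(self, random_df):
        fe = fit_cox(random_df, ["x", "x2"], ties="efron")
        fb = fit_cox(random_df, ["x", "x2"], ties="breslow")
        assert np.allclose(fe.coef, fb.coef, atol=1e-10)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)

    def test_within_stratum_shift_only(self, random_df):
        df1 = random_df.assign(g=np.arange(len(random_df)) % 2)
        df2 = df1.copy()
        df2.loc[df2["g"] == 1, "stop"] += 50.0
        f1 = fit_cox(df1, ["x", "x2"], strata_col="g")
        f2 = fit_cox(df2, ["x", "x2"], strata_col="g")
        assert np.allclose(f1.coef, f2.coef, atol=1e-9)

    def test_partial_loglik_helper_agrees_at_fit(self, random_df):
        fit = fit_cox(random_df, ["x", "x2"])
        ll = partial_loglik(random_df, ["x", "x2"], fit.coef)
        assert ll == pytest.approx(fit.loglik, abs=1e-10)


class TestRobustSandwich:
    def test_matches_score_residual_oracle_rowwise_clusters(self, random_df):
        df = random_df.drop(columns="x2").copy()
        df["cluster"] = np.arange(len(df))
        fit = fit_cox(df, ["x"], cluster_col="cluster")
        resid = brute_force_score_residuals(df, fit.coef[0])
        a_inv = fit.cov
        b = np.array([[np.sum(resid ** 2)]])
        oracle = a_inv @ b @ a_inv
        assert np.allclose(fit.robust_cov, oracle, atol=1e-8)
        # residuals sum to the score, which vanishes at the optimum
        assert abs(resid.sum()) < 1e-6

    def test_duplicating_the_full_stack_preserves_everything(self, random_df):
        df = random_df.copy()
        df["cluster"] = np.arange(len(df))
        fit = fit_cox(df, ["x", "x2"], strata_col=None, cluster_col="cluster")
        doubled = pd.concat([df.assign(g=0), df.assign(g=1)],
                            ignore_index=True)
        fit2 = fit_cox(doubled, ["x", "x2"], strata_col="g",
                       cluster_col="cluster")
        assert np.allclose(fit.coef, fit2.coef, atol=1e-8)
        # A doubles and B (cluster sums double, squared) quadruples:
        # the sandwich is unchanged while the naive variance halves
        assert np.allclose(fit.robust_cov, fit2.robust_cov, atol=1e-8)
        assert np.allclose(fit2.cov, fit.cov / 2, atol=1e-8)

    def test_duplicating_subjects_as_new_clusters_shrinks_robust_se(
            self, random_df):
        df = random_df.copy()
        df["cluster"] = np.arange(len(df))
        fit = fit_cox(df, ["x", "x2"], cluster_col="cluster")
        dup = df.copy()
        dup["cluster"] = dup["cluster"] + len(df)
        doubled = pd.concat([df.assign(g=0), dup.assign(g=1)],
                            ignore_index=True)
        fit2 = fit_cox(doubled, ["x", "x2"], strata_col="g",
                       cluster_col="cluster")
        assert np.allclose(fit.coef, fit2.coef, atol=1e-8)
        ratio = fit2.robust_se / fit.robust_se
        assert np.allclose(ratio, 1 / np.sqrt(2), atol=1e-10)

    def test_single_cluster_gives_rank_one_meat(self, random_df):
        df = random_df.copy()
        df["cluster"] = 0
        fit = fit_cox(df, ["x", "x2"], cluster_col="cluster")
        # recover B = A robust A from the sandwich and check its rank
        a = np.linalg.inv(fit.cov)
        b = a @ fit.robust_cov @ a
        eig = np.linalg.eigvalsh(b)
        assert np.sum(eig > 1e-8 * eig.max()) == 1

    def test_fewer_clusters_than_covariates_warns(self, random_df, caplog):
        df = random_df.copy()
        df["cluster"] = 0
        fit = fit_cox(df, ["x", "x2"])
        with caplog.at_level("WARNING"):
            robust_sandwich(fit, df, cluster_col="cluster")
        assert "unstable" in caplog.text
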