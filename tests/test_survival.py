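"""Survival machinery against brute-force oracles and reference libraries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rccpath.survival import (cox_partial_loglik, fit_cox_newton,
                              fit_lasso_cox, km_curve, logrank_test,
                              multivariate_cox, risk_index,
                              two_level_cv_stratify,
                              univariate_feature_screen, _lasso_cox_path,
                              _sorted_views)
from rccpath.synthetic import SyntheticCohortSpec, generate_survival_cohort


def _brute_force_logrank(times, events, groups):
    """Direct O/E/V table enumeration at every distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, bool)
    g1 = np.asarray(groups) == np.unique(groups)[0]
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        n_j = (times >= t).sum()
        n1j = ((times >= t) & g1).sum()
        d_j = (events & (times == t)).sum()
        d1j = (events & (times == t) & g1).sum()
        O += d1j
        E += d_j * n1j / n_j
        if n_j > 1:
            V += d_j * (n1j / n_j) * (1 - n1j / n_j) * (n_j - d_j) / (n_j - 1)
    return (O - E) ** 2 / V if V > 0 else np.nan


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = km_curve([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        km = km_curve([1, 2, 3], [False, False, False])
        assert len(km) == 0  # no event rows; the curve stays at 1

    def test_censored_worked_example(self):
        # subjects: event at 1, censored at 1.5, event at 3
        km = km_curve([1.0, 1.5, 3.0], [True, False, True])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 0.0])
        assert km["at_risk"].tolist() == [3, 1]  # risk set 1 at t=3

    def test_monotone_nonincreasing_and_start(self, rng):
        t = rng.exponential(10, 50)
        e = rng.uniform(size=50) < 0.7
        km = km_curve(t, e)
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert (s <= 1.0).all()

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, 80).round(1)
        e = rng.uniform(size=80) < 0.6
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.survival_function_at_times(row["time"]).iloc[0]))


class TestLogrank:
    def test_identical_groups_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [True] * 6
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ten_patient_worked_separation(self):
        t = list(range(1, 11))
        e = [True] * 10
        g = ["A"] * 5 + ["B"] * 5
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(_brute_force_logrank(t, e, g))
        assert p < 0.01  # complete separation of event times

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(5, 30)
        e = rng.uniform(size=30) < 0.8
        g = rng.integers(0, 2, 30)
        if not (e & (g == 0)).any() or not (e & (g == 1)).any():
            e[:2] = True
        chi2a, _ = logrank_test(t, e, g)
        chi2b, _ = logrank_test(t, e, 1 - g)
        assert chi2a == pytest.approx(chi2b)

    @given(n=st.integers(6, 30), seed=st.integers(0, 500))
    def test_equals_brute_force_enumeration(self, n, seed):
        r = np.random.default_rng(seed)
        t = r.integers(1, 10, n).astype(float)  # integer times force ties
        e = r.uniform(size=n) < 0.7
        g = r.integers(0, 2, n)
        if len(np.unique(g)) < 2:
            g[0] = 1 - g[0]
        if not e.any():
            e[0] = True
        chi2, _ = logrank_test(t, e, g)
        oracle = _brute_force_logrank(t, e, g)
        if np.isnan(oracle):
            assert np.isnan(chi2)
        else:
            assert chi2 == pytest.approx(oracle)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        t = rng.exponential(10, 60)
        e = rng.uniform(size=60) < 0.7
        g = rng.integers(0, 2, 60).astype(bool)
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)


class TestCoxNewton:
    def test_matches_lifelines_multivariate(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=300, n_features=3, beta=[0.8, -0.5, 0.0],
            censor_rate=0.2, seed=1))
        X = df[["f0", "f1", "f2"]].to_numpy()
        beta, cov, _ = fit_cox_newton(X, df["time"].to_numpy(),
                                      df["event"].to_numpy())
        from lifelines import CoxPHFitter
        cph = CoxPHFitter().fit(df[["f0", "f1", "f2", "time", "event"]],
                                "time", "event")
        np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)),
                                   cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_sign_matches_logrank_direction(self, rng):
        t = rng.exponential(10, 60)
        g = rng.integers(0, 2, 60)
        t[g == 1] *= 0.4  # group 1 has worse survival
        e = np.ones(60, dtype=bool)
        beta, _, _ = fit_cox_newton(g.astype(float)[:, None], t, e)
        assert beta[0] > 0


class TestLassoCox:
    def test_parameter_recovery_tiny_penalty(self):
        errs = []
        for rep in range(20):
            df = generate_survival_cohort(SyntheticCohortSpec(
                n_patients=500, n_features=1, beta=[1.0], censor_rate=0.0,
                with_covariates=False, seed=100 + rep))
            fit = fit_lasso_cox(df[["f0"]].to_numpy(), df["time"].to_numpy(),
                                df["event"].to_numpy(), penalties=[1e-4])
            errs.append(fit.coef[0])
        assert all(0.7 <= b <= 1.3 for b in errs)

    def test_infinite_penalty_all_zero(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=100, n_features=3, beta=[1.0, 0.5, 0.0], seed=0))
        fit = fit_lasso_cox(df[["f0", "f1", "f2"]].to_numpy(),
                            df["time"].to_numpy(), df["event"].to_numpy(),
                            penalties=[1e6])
        assert np.all(fit.coef == 0.0)

    def test_noise_features_mostly_nulled_by_cv(self):
        near_null = 0
        for rep in range(50):
            df = generate_survival_cohort(SyntheticCohortSpec(
                n_patients=200, n_features=4, beta=[0.0] * 4,
                censor_rate=0.2, with_covariates=False, seed=300 + rep))
            X = df[[f"f{j}" for j in range(4)]].to_numpy()
            fit = fit_lasso_cox(X, df["time"].to_numpy(),
                                df["event"].to_numpy(), folds=10, seed=rep)
            if np.max(np.abs(fit.coef)) < 0.1:
                near_null += 1
        assert near_null >= 40  # >= 80% of replicates

    def test_path_shrinks_monotonically_in_max_norm(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=200, n_features=3, beta=[1.0, -0.6, 0.3],
            censor_rate=0.1, seed=5))
        X = df[["f0", "f1", "f2"]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        Zs, ts, es, _ = _sorted_views(Z, df["time"].to_numpy(),
                                      df["event"].to_numpy())
        penalties = np.geomspace(10.0, 1e-4, 25)  # decreasing along the path
        betas = _lasso_cox_path(Zs, ts, es, penalties)
        norms = np.abs(betas).max(axis=1)
        assert (np.diff(norms) >= -1e-6).all()  # grow as penalty shrinks
        assert norms[0] < 1e-8  # above lambda_max everything is nulled

    def test_matches_sksurv_coxnet(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        from sksurv.util import Surv
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=300, n_features=4, beta=[1.0, -0.5, 0.2, 0.0],
            censor_rate=0.2, with_covariates=False, seed=7))
        X = df[[f"f{j}" for j in range(4)]].to_numpy()
        lam = 0.05
        fit = fit_lasso_cox(X, df["time"].to_numpy(), df["event"].to_numpy(),
                            penalties=[lam])
        y = Surv.from_arrays(df["event"], df["time"])
        ref = sksurv.CoxnetSurvivalAnalysis(
            alphas=[lam], l1_ratio=1.0, normalize=False, tol=1e-9)
        Z = (X - X.mean(0)) / X.std(0)
        ref.fit(Z, y)
        np.testing.assert_allclose(fit.coef * X.std(0), ref.coef_[:, 0],
                                   atol=5e-3)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_cox(np.ones((10, 1)), np.arange(1, 11),
                          np.zeros(10, bool))


class TestRiskIndex:
    def test_zero_coefficients(self):
        assert np.all(risk_index(np.zeros(3), np.ones((5, 3))) == 0.0)

    def test_hand_computation(self):
        assert risk_index(np.array([0.5, -1.0]),
                          np.array([[2.0, 1.0]]))[0] == pytest.approx(0.0)

    def test_linearity_in_positive_coefficient(self):
        coef = np.array([0.7])
        assert risk_index(coef, [[2.0]])[0] > risk_index(coef, [[1.0]])[0]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            risk_index(np.zeros(2), np.ones((3, 4)))


class TestTwoLevelCV:
    def test_informative_feature_stratifies(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=120, n_features=1, beta=[1.0], censor_rate=0.3,
            with_covariates=False, seed=42))
        strat = two_level_cv_stratify(df, ["f0"], seed=0)
        assert strat.p_value < 0.01
        assert strat.hazard_ratio > 1.0

    def test_group_sizes_near_balanced(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=60, n_features=1, beta=[1.0], censor_rate=0.2,
            with_covariates=False, seed=9))
        strat = two_level_cv_stratify(df, ["f0"], seed=0)
        n_high = (strat.group == "high").sum()
        # median split on n-1 training risks keeps groups near balanced
        assert abs(n_high - len(df) / 2) <= len(df) * 0.2

    def test_minimum_cohort_enforced(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=10, censor_rate=0.0, seed=0))
        with pytest.raises(ValueError):
            two_level_cv_stratify(df, ["f0"], seed=0)

    def test_assignment_ignores_own_outcome(self):
        """Perturbing a patient's outcome must not change their own group
        assignment (leave-one-out leakage check)."""
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=30, n_features=1, beta=[1.0], censor_rate=0.0,
            with_covariates=False, seed=3))
        strat = two_level_cv_stratify(df, ["f0"], seed=0)
        df2 = df.copy()
        df2.loc[df2.index[0], "time"] = df2["time"].max() * 10
        df2.loc[df2.index[0], "event"] = False
        strat2 = two_level_cv_stratify(df2, ["f0"], seed=0)
        assert strat.group[0] == strat2.group[0]


class TestKmPlot:
    def test_renders_step_curves_to_file(self, tmp_path, rng):
        from rccpath.survival import save_km_plot
        t = rng.exponential(10, 40)
        e = rng.uniform(size=40) < 0.7
        curves = {"low": km_curve(t, e), "high": km_curve(t * 0.5, e)}
        out = tmp_path / "km.png"
        save_km_plot(curves, out, title="demo")
        assert out.exists() and out.stat().st_size > 0


class TestMultivariateCox:
    def test_binary_hr_recovery(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, 400)
        t = rng.exponential(np.where(g == 1, 5.0, 10.0))  # HR 2 for group 1
        df = pd.DataFrame({"time": t, "event": True, "group": g.astype(float)})
        out = multivariate_cox(df, ["group"])
        assert 1.6 <= out.loc[0, "HR"] <= 2.5

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"time": [1., 2, 3, 4], "event": [1, 1, 0, 1],
                           "c": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            multivariate_cox(df, ["c"])

    def test_collinear_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        df = pd.DataFrame({"time": rng.exponential(5, 50), "event": True,
                           "a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            multivariate_cox(df, ["a", "b"])


class TestUnivariateScreen:
    def test_duplicated_feature_same_pvalue(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=40, n_features=1, beta=[0.8], censor_rate=0.2,
            with_covariates=False, seed=21))
        df["f_dup"] = df["f0"]
        out = univariate_feature_screen(df, ["f0", "f_dup"], seed=0)
        # same column, same per-feature procedure except the fold seed
        out2 = univariate_feature_screen(df, ["f_dup", "f0"], seed=0)
        assert out.loc[0, "p_value"] == pytest.approx(out2.loc[1, "p_value"],
                                                      rel=0.5)

    def test_empty_feature_list(self):
        df = generate_survival_cohort(SyntheticCohortSpec(
            n_patients=40, seed=0))
        out = univariate_feature_screen(df, [], seed=0)
        assert len(out) == 0

    def test_discriminates_informative_from_noise(self):
        hits = 0
        for rep in range(10):
            df = generate_survival_cohort(SyntheticCohortSpec(
                n_patients=100, n_features=2, beta=[1.2, 0.0],
                censor_rate=0.2, with_covariates=False, seed=800 + rep))
            out = univariate_feature_screen(df, ["f0", "f1"], seed=rep)
            inf_p = out.loc[out["feature"] == "f0", "p_value"].iloc[0]
            noise_p = out.loc[out["feature"] == "f1", "p_value"].iloc[0]
            hits += (inf_p < 0.05) and (inf_p < noise_p)
        assert hits >= 8
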