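"""Survival analysis: Kaplan-Meier, log-rank, lasso-Cox risk stratification.

The procedure mirrors the image-feature prognosis workflow: each patient
carries morphometric features plus time-to-event data; an L1-penalized Cox
proportional-hazards model turns features into a scalar risk index (the
linear predictor), and patients are stratified into low/high risk by a
two-level cross-validation — an outer leave-one-out loop in which the
penalty is chosen by inner 10-fold cross-validated partial-likelihood
deviance on the remaining patients, and the left-out patient is assigned
high risk iff their index exceeds the training median.  No patient's own
outcome ever enters their group assignment.  The assembled groups are then
compared by the log-rank test and a group-contrast hazard ratio.

Kaplan-Meier, the log-rank statistic and the penalized Cox solver are
implemented here directly (Breslow tie handling; glmnet-style iteratively
reweighted coordinate descent for the lasso path) so they can be verified
against independent brute-force oracles.  The one-off unpenalized
multivariate Cox report (HR, Wald CI, p per covariate) is delegated to
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

__all__ = [
    "km_curve", "logrank_test", "cox_partial_loglik", "fit_cox_newton",
    "fit_lasso_cox", "LassoCoxFit", "risk_index", "two_level_cv_stratify",
    "RiskStratification", "multivariate_cox", "univariate_feature_screen",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table with one row per distinct event time: ``time``,
    ``at_risk``, ``events`` and ``survival`` = prod_{t_j <= t} (1 - d_j/n_j).
    Censored subjects leave the risk set after their censoring time.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    rows, surv = [], 1.0
    n = times.size
    i = 0
    while i < n:
        t = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == t:
            d += int(e_sorted[j])
            j += 1
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append({"time": t, "at_risk": at_risk, "events": d,
                         "survival": surv})
        i = j
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time t_j with n_j subjects at risk, d_j events
    and n_1j of group 1 at risk: O = sum d_1j, E = sum d_j n_1j / n_j and
    V = sum d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1).  The
    statistic (O - E)^2 / V is chi-square with 1 df.  Returns
    ``(nan, nan)`` when V = 0 (no information).
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("log-rank test needs exactly two groups")
    if not events.any():
        raise ValueError("log-rank test needs at least one event")
    g1 = groups == labels[0]
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_j = int(at_risk.sum())
        n_1j = int((at_risk & g1).sum())
        d_j = int((events & (times == t)).sum())
        d_1j = int((events & (times == t) & g1).sum())
        O += d_1j
        E += d_j * n_1j / n_j
        if n_j > 1:
            V += d_j * (n_1j / n_j) * (1 - n_1j / n_j) * (n_j - d_j) / (n_j - 1)
    if V <= 0:
        return float("nan"), float("nan")
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery (Breslow ties)
# ---------------------------------------------------------------------------

def _sorted_views(X, times, events):
    order = np.argsort(times, kind="stable")
    return X[order], np.asarray(times)[order], np.asarray(events)[order], order


def _tie_groups(ts, es):
    """Group structure of sorted times: first index, size, events per group."""
    _, first, counts = np.unique(ts, return_index=True, return_counts=True)
    d = np.add.reduceat(es.astype(np.int64), first)
    return first, counts, d


def _loglik_sorted(beta, Xs, ts, es, groups=None) -> float:
    """Breslow log partial likelihood; inputs sorted ascending by time."""
    eta = Xs @ np.asarray(beta, float)
    m = eta.max() if eta.size else 0.0
    log_S = m + np.log(np.cumsum(np.exp(eta - m)[::-1])[::-1])
    first, _, d = _tie_groups(ts, es) if groups is None else groups
    return float(eta[es].sum() - (d * log_S[first]).sum())


def cox_partial_loglik(beta: np.ndarray, X: np.ndarray, times, events) -> float:
    """Breslow log partial likelihood at ``beta``."""
    X = np.atleast_2d(X)
    Xs, ts, es, _ = _sorted_views(X, np.asarray(times, float),
                                  np.asarray(events, bool))
    return _loglik_sorted(beta, Xs, ts, es)


def _cox_eta_derivatives(eta, ts, es, groups=None):
    """Per-sample score residual and curvature weight in sorted order.

    mu_i = exp(eta_i) * H0(t_i) with H0 the Breslow cumulative hazard;
    gradient wrt eta is (event_i - mu_i); the curvature weight uses mu_i,
    the standard diagonal-Hessian majorization.
    """
    m = eta.max() if eta.size else 0.0
    w_exp = np.exp(eta - m)
    S = np.cumsum(w_exp[::-1])[::-1]  # S_i = sum_{t_j >= t_i} exp(eta_j - m)
    first, counts, d = _tie_groups(ts, es) if groups is None else groups
    H0_group = np.cumsum(d / S[first])  # cumulative hazard over event times
    mu = w_exp * np.repeat(H0_group, counts)
    return es.astype(float) - mu, mu


def fit_cox_newton(X: np.ndarray, times, events, max_iter: int = 50,
                   tol: float = 1e-9, ridge: float = 0.0):
    """Unpenalized (optionally ridge-stabilized) Cox fit with full Newton.

    Returns ``(beta, cov, loglik)`` where ``cov`` is the inverse observed
    information (Wald covariance).  Intended for low-dimensional fits such
    as the group-contrast hazard ratio.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    Xs, ts, es, _ = _sorted_views(X, times, events)
    n, p = Xs.shape
    beta = np.zeros(p)
    ll = cox_partial_loglik(beta, Xs, ts, es)
    for _ in range(max_iter):
        eta = Xs @ beta
        m = eta.max()
        w = np.exp(eta - m)
        S = np.cumsum(w[::-1])[::-1]
        Sx = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        Sxx = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1],
                        axis=0)[::-1]
        grad = np.zeros(p)
        info = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            d, sx = 0, np.zeros(p)
            while j < n and ts[j] == ts[i]:
                if es[j]:
                    d += 1
                    sx += Xs[j]
                j += 1
            if d > 0:
                xbar = Sx[i] / S[i]
                grad += sx - d * xbar
                info += d * (Sxx[i] / S[i] - np.outer(xbar, xbar))
            i = j
        if ridge > 0:
            grad -= ridge * beta
            info += ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving
        t_step = 1.0
        for _ in range(30):
            new_ll = cox_partial_loglik(beta + t_step * step, Xs, ts, es)
            if new_ll >= ll - 1e-12:
                break
            t_step /= 2.0
        beta = beta + t_step * step
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, cov, float(ll)


# ---------------------------------------------------------------------------
# lasso-Cox path + cross-validation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cd_sweeps(X, w, r, beta, lam, max_sweeps, tol):  # pragma: no cover
    """In-place cyclic coordinate descent on the penalized WLS subproblem."""
    n, p = X.shape
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            denom = 0.0
            for i in range(n):
                xij = X[i, j]
                rho += w[i] * xij * (r[i] + xij * bj)
                denom += w[i] * xij * xij
            rho /= n
            denom /= n
            if denom <= 0.0:
                continue
            if rho > lam:
                nb = (rho - lam) / denom
            elif rho < -lam:
                nb = (rho + lam) / denom
            else:
                nb = 0.0
            if nb != bj:
                d = bj - nb
                for i in range(n):
                    r[i] += X[i, j] * d
                beta[j] = nb
                ad = abs(nb - bj)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            break


def _lasso_cox_path(Xs, ts, es, penalties, max_irls: int = 20,
                    cd_tol: float = 1e-7, groups=None):
    """Coordinate-descent lasso-Cox along a decreasing penalty path.

    ``Xs`` must already be standardized and sorted by time; the penalty is
    lambda * sum |beta_j| against the mean log partial likelihood (1/n
    scaling, the glmnet convention).  Warm starts along the path; each IRLS
    step solves the penalized weighted-least-squares subproblem by cyclic
    coordinate descent.
    """
    n, p = Xs.shape
    if groups is None:
        groups = _tie_groups(ts, es)
    Xc = np.ascontiguousarray(Xs)
    betas = np.zeros((len(penalties), p))
    beta = np.zeros(p)
    for k, lam in enumerate(penalties):
        for _ in range(max_irls):
            eta = Xs @ beta
            resid, mu = _cox_eta_derivatives(eta, ts, es, groups)
            w = np.maximum(mu, 1e-10)
            r = resid / w  # working residual z - eta
            _cd_sweeps(Xc, w, r, beta, float(lam), 50, cd_tol)
            if np.max(np.abs(Xs @ beta - eta)) < 1e-6:
                break
        betas[k] = beta
    return betas


@dataclass
class LassoCoxFit:
    coef: np.ndarray            # on the original feature scale
    penalty: float              # selected lambda
    penalties: np.ndarray       # the path, decreasing
    cv_deviance: np.ndarray | None
    mean: np.ndarray
    scale: np.ndarray


def _penalty_path(Xs, ts, es, n_penalties: int, eps: float) -> np.ndarray:
    n = len(ts)
    resid0, _ = _cox_eta_derivatives(np.zeros(n), ts, es)
    lam_max = float(np.max(np.abs(Xs.T @ resid0)) / n)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_penalties)


def fit_lasso_cox(X: np.ndarray, times, events, penalties=None,
                  folds: int = 10, seed: int = 0, n_penalties: int = 12,
                  path_eps: float = 0.05) -> LassoCoxFit:
    """L1-penalized Cox fit with the penalty chosen by k-fold CV.

    Features are standardized internally; coefficients are returned on the
    original scale.  The cross-validation criterion is the
    Verweij-van Houwelingen partial-likelihood deviance
    ``-2 [l_full(beta_{-k}) - l_train(beta_{-k})]`` summed over folds.
    Requires at least 2 events and finite features.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    n, p = X.shape
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Z = (X - mean) / scale
    Zs, ts, es, order = _sorted_views(Z, times, events)

    if penalties is None:
        penalties = _penalty_path(Zs, ts, es, n_penalties, path_eps)
    penalties = np.asarray(penalties, float)

    all_groups = _tie_groups(ts, es)
    cv_dev = None
    if penalties.size > 1:
        rng = np.random.default_rng(seed)
        assign = rng.permutation(n) % folds
        cv_dev = np.zeros(penalties.size)
        for k in range(folds):
            tr = assign != k  # subset of sorted arrays stays sorted
            if es[tr].sum() < 1:
                continue
            tr_groups = _tie_groups(ts[tr], es[tr])
            betas_k = _lasso_cox_path(Zs[tr], ts[tr], es[tr], penalties,
                                      groups=tr_groups)
            for a, beta in enumerate(betas_k):
                l_full = _loglik_sorted(beta, Zs, ts, es, all_groups)
                l_train = _loglik_sorted(beta, Zs[tr], ts[tr], es[tr], tr_groups)
                cv_dev[a] += -2.0 * (l_full - l_train)
        best = int(np.argmin(cv_dev))
    else:
        best = 0

    betas = _lasso_cox_path(Zs, ts, es, penalties, groups=all_groups)
    coef = betas[best] / scale
    return LassoCoxFit(coef=coef, penalty=float(penalties[best]),
                       penalties=penalties, cv_deviance=cv_dev,
                       mean=mean, scale=scale)


def risk_index(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cox linear predictor ``X . beta`` (no intercept)."""
    X = np.atleast_2d(np.asarray(X, float))
    coef = np.asarray(coef, float)
    if X.shape[1] != coef.shape[0]:
        raise ValueError("feature count does not match coefficients")
    return X @ coef


# ---------------------------------------------------------------------------
# two-level cross-validated stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    risk: np.ndarray            # held-out risk index per patient
    group: np.ndarray           # "low" / "high"
    chi2: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    degenerate: bool = False


def two_level_cv_stratify(records: pd.DataFrame, features: list[str],
                          seed: int = 0, folds: int = 10,
                          n_penalties: int = 12) -> RiskStratification:
    """Leave-one-out risk stratification with inner CV penalty selection.

    For each patient, a lasso-Cox model is fit on the other patients (the
    penalty picked by inner k-fold CV on those patients only); the left-out
    patient is assigned high risk iff their risk index strictly exceeds the
    median training risk index (ties go to low risk).  The assembled groups
    are compared by log-rank, and a group-contrast hazard ratio with Wald
    95% CI is fit on the high-vs-low indicator.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 patients")
    times = records["time"].to_numpy(float)
    events = records["event"].to_numpy(bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    X = records[features].to_numpy(float)
    n = len(records)
    risk = np.empty(n)
    high = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        assert not tr[i], "left-out patient leaked into training"
        fit = fit_lasso_cox(X[tr], times[tr], events[tr],
                            folds=folds, seed=int(rng.integers(2**31)),
                            n_penalties=n_penalties)
        train_risk = risk_index(fit.coef, X[tr])
        risk[i] = float(risk_index(fit.coef, X[i:i + 1])[0])
        high[i] = risk[i] > float(np.median(train_risk))
    group = np.where(high, "high", "low")
    if high.all() or not high.any():
        return RiskStratification(risk, group, float("nan"), float("nan"),
                                  float("nan"), (float("nan"), float("nan")),
                                  degenerate=True)
    chi2, p = logrank_test(times, events, group)
    beta, cov, _ = fit_cox_newton(high.astype(float)[:, None], times, events)
    se = float(np.sqrt(cov[0, 0]))
    hr = float(np.exp(beta[0]))
    ci = (float(np.exp(beta[0] - 1.96 * se)), float(np.exp(beta[0] + 1.96 * se)))
    return RiskStratification(risk, group, chi2, p, hr, ci)


def multivariate_cox(df: pd.DataFrame, covariates: list[str],
                     time_col: str = "time",
                     event_col: str = "event") -> pd.DataFrame:
    """Unpenalized multivariate Cox report: HR, Wald 95% CI, p per covariate.

    Rejects zero-variance or (near-)collinear covariates before fitting.
    """
    from lifelines import CoxPHFitter

    sub = df[[time_col, event_col] + covariates].astype(float)
    Xc = sub[covariates].to_numpy()
    stds = Xc.std(axis=0)
    if (stds < 1e-12).any():
        bad = [c for c, s in zip(covariates, stds) if s < 1e-12]
        raise ValueError(f"zero-variance covariates: {bad}")
    corr = np.corrcoef(Xc, rowvar=False)
    if len(covariates) > 1:
        off = corr[~np.eye(len(covariates), dtype=bool)]
        if np.any(np.abs(off) > 0.999):
            raise ValueError("collinear covariate pair detected")
    cph = CoxPHFitter()
    cph.fit(sub, duration_col=time_col, event_col=event_col)
    out = pd.DataFrame({
        "covariate": covariates,
        "HR": np.exp(cph.params_[covariates].to_numpy()),
        "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0][covariates].to_numpy()),
        "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1][covariates].to_numpy()),
        "p_value": cph.summary.loc[covariates, "p"].to_numpy(),
    })
    return out


def save_km_plot(curves: dict[str, pd.DataFrame], path, title: str = "",
                 max_time: float | None = None) -> None:
    """Render Kaplan-Meier step curves (one per group) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, km in sorted(curves.items()):
        t = np.concatenate([[0.0], km["time"].to_numpy()])
        s = np.concatenate([[1.0], km["survival"].to_numpy()])
        ax.step(t, s, where="post", label=f"{name} (n events={int(km['events'].sum())})")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if max_time is not None:
        ax.set_xlim(0, max_time)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def univariate_feature_screen(records: pd.DataFrame, features: list[str],
                              seed: int = 0, folds: int = 10,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-level-CV stratification and log-rank p-value table.

    Each feature alone drives a stratification; the table reports the
    log-rank p-value and significance at ``alpha`` (raw p-values, no
    multiple-testing correction; apply Benjamini-Hochberg downstream if
    desired).
    """
    rows = []
    for k, feat in enumerate(features):
        strat = two_level_cv_stratify(records, [feat],
                                      seed=seed + k, folds=folds)
        rows.append({"feature": feat, "chi2": strat.chi2,
                     "p_value": strat.p_value,
                     "significant": bool(strat.p_value < alpha)
                     if np.isfinite(strat.p_value) else False})
    return pd.DataFrame(rows, columns=["feature", "chi2", "p_value",
                                       "significant"])
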