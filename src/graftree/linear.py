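"""Comparison models: Cox proportional hazards and logistic regression.

Both are implemented directly (Newton-Raphson on the Breslow partial
likelihood; iteratively reweighted least squares for the logistic model) so
their small-sample behaviour can be checked against brute-force likelihood
grids. Covariates are standardized internally for numerical stability and
coefficients are reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinearModelFit",
    "CoxPH",
    "WeightedLogisticRegression",
    "fit_cox",
    "fit_logistic",
    "encode_design",
]

# A coefficient above 10 on the standardized scale (odds/hazard ratio e^10
# per sd) only arises under a monotone likelihood; treated as separation.
_MAX_ABS_STD_COEF = 10.0


@dataclass
class LinearModelFit:
    """Coefficient report of a fitted linear model (log-HR for Cox,
    log-odds for logistic)."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    intercept: float | None
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: list = field(default_factory=list)

    def to_records(self):
        return [
            {"covariate": n, "coef": float(b), "se": float(s), "hr": float(np.exp(b))}
            for n, b, s in zip(self.names, self.coef, self.se)
        ]


def encode_design(X) -> tuple[np.ndarray, list]:
    """Numeric design matrix: numeric columns pass through, categorical ones
    are dummy-coded dropping the first level."""
    if isinstance(X, pd.DataFrame):
        enc = pd.get_dummies(X, drop_first=True, dtype=float)
        return enc.to_numpy(dtype=float), list(enc.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _standardize(Z):
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Z - mu) / sd, mu, sd


class CoxPH:
    """Cox proportional-hazards model (Breslow ties, Newton-Raphson).

    Convergence when the maximum score component (standardized scale) falls
    below ``tol`` or after ``max_iter`` iterations; a monotone likelihood
    (separation) is flagged as non-converged with a warning. ``predict``
    returns the linear predictor (risk score).
    """

    def __init__(self, *, tol=1e-8, max_iter=50):
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return dict(tol=self.tol, max_iter=self.max_iter)

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, *, time=None, event=None):
        from .tree.survival import _resolve_outcome

        t, e = _resolve_outcome(y, time, event)
        Z, names = encode_design(X)
        if int(e.sum()) < 1:
            raise ValueError("Cox fit requires at least one event")
        if np.isnan(Z).any():
            raise ValueError("design matrix has missing values; impute or drop rows")
        Zs, mu, sd = _standardize(Z)
        beta, info, ll, path, n_iter, converged = self._newton(Zs, t, e)
        if not converged:
            warnings.warn(
                "Cox Newton-Raphson did not converge (possible monotone "
                "likelihood / separation); coefficients may diverge",
                stacklevel=2,
            )
        cov = np.linalg.pinv(info)
        se_std = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.coef_ = beta / sd
        self.se_ = se_std / sd
        self.names_ = names
        self.loglik_ = ll
        self.converged_ = converged
        self.n_iter_ = n_iter
        self._mu, self._sd, self._beta_std = mu, sd, beta
        self.fit_ = LinearModelFit(names, self.coef_, self.se_, None,
                                   converged, n_iter, ll, path)
        return self

    # Breslow partial likelihood machinery ---------------------------------
    @staticmethod
    def _ll_score_info(Z, t, e, beta):
        """Log-likelihood, score and information in one descending-time pass;
        risk-set sums S0/S1/S2 are accumulated blockwise between event
        times (Breslow: tied events share the full risk set)."""
        order = np.argsort(-t, kind="mergesort")
        Zo, to, eo = Z[order], t[order], e[order]
        n, p = Zo.shape
        eta = Zo @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and to[j] == to[i]:
                j += 1
            blk = slice(i, j)
            S0 += float(w[blk].sum())
            S1 += w[blk] @ Zo[blk]
            S2 += Zo[blk].T @ (w[blk][:, None] * Zo[blk])
            ev = blk.start + np.flatnonzero(eo[blk] == 1)
            d = len(ev)
            if d:
                xbar = S1 / S0
                ll += float(eta[ev].sum()) - d * np.log(S0)
                score += Zo[ev].sum(axis=0) - d * xbar
                info += d * (S2 / S0 - np.outer(xbar, xbar))
            i = j
        return ll, score, info

    def _newton(self, Z, t, e):
        p = Z.shape[1]
        beta = np.zeros(p)
        ll, score, info = self._ll_score_info(Z, t, e, beta)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
            # step halving keeps the likelihood nondecreasing (up to float noise)
            for _ in range(30):
                ll_new, score_new, info_new = self._ll_score_info(Z, t, e, beta + step)
                if ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                    break
                step *= 0.5
            beta = beta + step
            ll, score, info = ll_new, score_new, info_new
            path.append(ll)
            if np.max(np.abs(beta)) > _MAX_ABS_STD_COEF:
                converged = False
                break
        else:
            converged = bool(np.max(np.abs(score)) < self.tol)
        if np.max(np.abs(beta)) > _MAX_ABS_STD_COEF:
            converged = False
        elif np.max(np.abs(score)) < self.tol:
            converged = True
        return beta, info, ll, path, it, converged

    def predict(self, X):
        Z, _ = encode_design(X)
        return (Z - self._mu) / self._sd @ self._beta_std


class WeightedLogisticRegression:
    """Logistic regression by IRLS with instance weights (Zupan-compatible).

    ``pi(x) = 1 / (1 + exp(-(b0 + b.x)))``; scores are predicted
    probabilities. Complete separation is flagged as non-converged.
    """

    def __init__(self, *, tol=1e-8, max_iter=50, fit_intercept=True):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def get_params(self, deep=True):
        return dict(tol=self.tol, max_iter=self.max_iter, fit_intercept=self.fit_intercept)

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, sample_weight=None):
        Z, names = encode_design(X)
        y = np.asarray(y, dtype=float)
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if (w * y).sum() <= 0 or (w * (1 - y)).sum() <= 0:
            raise ValueError("both classes must be present with positive weight")
        Zs, mu, sd = _standardize(Z)
        if self.fit_intercept:
            Zs = np.column_stack([np.ones(len(y)), Zs])
        p_dim = Zs.shape[1]
        beta = np.zeros(p_dim)
        converged = False
        ll = -np.inf
        path = []
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = np.clip(Zs @ beta, -30, 30)
            pi = 1.0 / (1.0 + np.exp(-eta))
            score = Zs.T @ (w * (y - pi))
            ll = float(np.sum(w * (y * np.log(pi + 1e-300) + (1 - y) * np.log(1 - pi + 1e-300))))
            path.append(ll)
            W = w * pi * (1 - pi)
            H = Zs.T @ (W[:, None] * Zs)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(p_dim), score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, score, rcond=None)[0]
            beta = beta + step
            if np.max(np.abs(beta)) > _MAX_ABS_STD_COEF:
                converged = False
                break
        if np.max(np.abs(beta)) > _MAX_ABS_STD_COEF:
            converged = False
        if not converged:
            warnings.warn("logistic IRLS did not converge (possible separation)", stacklevel=2)
        cov = np.linalg.pinv(H)
        se_std = np.sqrt(np.clip(np.diag(cov), 0, None))
        if self.fit_intercept:
            b0_std, b_std = beta[0], beta[1:]
            se0, se_b = se_std[0], se_std[1:]
        else:
            b0_std, b_std = 0.0, beta
            se0, se_b = 0.0, se_std
        self.coef_ = b_std / sd
        self.intercept_ = float(b0_std - np.sum(b_std * mu / sd))
        self.se_ = se_b / sd
        self.names_ = names
        self.loglik_ = ll
        self.converged_ = converged
        self.n_iter_ = it
        self._mu, self._sd, self._beta_std, self._b0_std = mu, sd, b_std, b0_std
        self.fit_ = LinearModelFit(names, self.coef_, self.se_, self.intercept_,
                                   converged, it, ll, path)
        return self

    def predict_proba(self, X):
        Z, _ = encode_design(X)
        eta = self._b0_std + (Z - self._mu) / self._sd @ self._beta_std
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return np.column_stack([1 - pi, pi])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_cox(cohort, covariates=None) -> CoxPH:
    """Fit a Cox model on a Cohort (complete-case on the chosen columns)."""
    X = cohort.data if covariates is None else cohort.data[list(covariates)]
    keep = ~X.isna().any(axis=1).to_numpy()
    return CoxPH().fit(X[keep], time=cohort.time[keep], event=cohort.event[keep])


def fit_logistic(X, labels, weights=None) -> WeightedLogisticRegression:
    """Fit weighted logistic regression on a labelled instance set."""
    return WeightedLogisticRegression().fit(X, labels, sample_weight=weights)
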