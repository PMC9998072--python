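"""OLS and right-censored Tobit mapping estimators.

OLS ignores the ceiling at full health; the Tobit model treats utilities at
the upper bound as right-censored observations of a latent Gaussian index,
so censored subjects contribute survival terms ``log(1 - Phi((u - x'b)/s))``
to the likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .base import (
    MappingResults,
    Standardizer,
    UtilityMappingModel,
    cov_from_hessian,
    find_collinear,
    param_index,
)

__all__ = ["OLSMapping", "TobitMapping"]

_LOG_2PI = np.log(2.0 * np.pi)


class OLSMapping(UtilityMappingModel):
    """Ordinary least squares on the raw utility scale."""

    def fit(self) -> MappingResults:
        import statsmodels.api as sm

        if self.nobs <= self.k_exog:
            raise ValueError("need more observations than parameters")
        if np.linalg.matrix_rank(self.exog) < self.k_exog:
            bad = find_collinear(self.exog, self.exog_names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
        res = sm.OLS(self.endog, self.exog).fit()
        sigma = float(np.sqrt(np.mean(res.resid**2)))  # MLE variance
        idx = param_index(
            [("mean", 1, n) for n in self.exog_names] + [("scale", 1, "sigma")]
        )
        params = pd.Series(np.append(res.params, sigma), index=idx)
        # sigma SE from Gaussian MLE asymptotics: sigma / sqrt(2n)
        bse = pd.Series(
            np.append(res.bse, sigma / np.sqrt(2.0 * self.nobs)), index=idx
        )
        return MappingResults(
            family="OLS",
            params=params,
            bse=bse,
            llf=float(res.llf),
            k_params=self.k_exog + 1,
            nobs=self.nobs,
            exog_names=self.exog_names,
        )


class TobitMapping(UtilityMappingModel):
    """Gaussian latent-index model, right-censored at ``upper`` (default 1)."""

    def __init__(self, endog, exog, upper: float = 1.0):
        super().__init__(endog, exog)
        self.upper = float(upper)
        self.censored = self.endog >= self.upper
        if self.censored.all():
            raise ValueError("all observations censored: coefficients unidentified")

    def _ll(self, theta: np.ndarray, X: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        xb = X @ beta
        z = (self.endog - xb) / sigma
        ll_unc = -0.5 * _LOG_2PI - log_sigma - 0.5 * z**2
        ll = np.where(self.censored, norm.logsf((self.upper - xb) / sigma), ll_unc)
        return float(ll.sum())

    def _score(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        xb = X @ beta
        z = (self.endog - xb) / sigma
        s = (self.upper - xb) / sigma
        hazard = np.exp(norm.logpdf(s) - norm.logsf(s))
        w_beta = np.where(self.censored, hazard, z) / sigma
        g_beta = X.T @ w_beta
        g_logsig = np.where(self.censored, hazard * s, z**2 - 1.0).sum()
        return np.append(g_beta, g_logsig)

    def loglike(self, theta: np.ndarray) -> float:
        """Censored-normal log-likelihood at raw-scale (beta, log sigma)."""
        return self._ll(theta, self.exog)

    def score(self, theta: np.ndarray) -> np.ndarray:
        return self._score(theta, self.exog)

    def fit(self, tol: float = 1e-12) -> MappingResults:
        # optimize on standardized covariates for conditioning
        std = Standardizer(self.exog)
        Xs = std.transform(self.exog)
        beta0, *_ = np.linalg.lstsq(Xs, self.endog, rcond=None)
        sigma0 = max(float(np.std(self.endog - Xs @ beta0)), 1e-3)
        start = np.append(beta0, np.log(sigma0))
        res = minimize(
            lambda t: -self._ll(t, Xs),
            start,
            jac=lambda t: -self._score(t, Xs),
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": tol, "gtol": 1e-10},
        )
        theta_std = res.x
        sigma = float(np.exp(theta_std[-1]))
        cov_std = cov_from_hessian(lambda t: -self._ll(t, Xs), theta_std)
        from scipy.linalg import block_diag

        T = block_diag(std.M, np.eye(1))
        beta_raw = std.raw_coef(theta_std[:-1])
        with np.errstate(invalid="ignore"):
            d = np.diag(T @ cov_std @ T.T)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        idx = param_index(
            [("mean", 1, n) for n in self.exog_names] + [("scale", 1, "sigma")]
        )
        params = pd.Series(np.append(beta_raw, sigma), index=idx)
        # delta method: se(sigma) = sigma * se(log sigma)
        bse = pd.Series(np.append(se[:-1], sigma * se[-1]), index=idx)
        converged = bool(res.success) and sigma > 1e-8
        return MappingResults(
            family="TOBIT",
            params=params,
            bse=bse,
            llf=float(-res.fun),
            k_params=self.k_exog + 1,
            nobs=self.nobs,
            exog_names=self.exog_names,
            converged=converged,
            options={"upper": self.upper},
        )
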