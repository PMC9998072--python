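"""One-inflated beta mixture regression for bounded utilities.

The utility is rescaled to the unit interval, ``y* = (y - u_min)/(1 - u_min)``
with ``u_min = -0.391`` (Chinese EQ-5D-5L tariff floor).  The model places a
degenerate probability mass at full health (``y* = 1``) governed by a
logistic regression, and below the ceiling a C-component mixture of beta
densities in the mean/precision parameterization, with a logit link on each
component mean:

    log L = sum_{y*=1} log L(g'x)
          + sum_{y*<1} [ log(1 - L(g'x)) + log sum_c pi_c f_B(y*; mu_c(x), phi_c) ]

where ``logit mu_c(x) = b_c'x`` and ``f_B(y; mu, phi)`` is Beta(mu*phi,
(1-mu)*phi).  Mixture weights are covariate-free (multinomial-logit
parameterized).  The truncated variant renormalizes each component to the
support (0, tau), tau being the rescaled largest observed non-ceiling
utility, dividing the density by the beta CDF at tau.

Estimation is direct maximization of the full log-likelihood (L-BFGS-B,
analytic gradient for the untruncated model) from multiple perturbed
moment-based starts.  Optimization runs on internally standardized
covariates for conditioning; reported coefficients are on the raw score
scale.  Components are reported in ascending order of the component mean at
the covariate mean to pin down labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import block_diag
from scipy.optimize import minimize
from scipy.special import betainc, expit, gammaln, log_expit, logsumexp, psi, softmax

from .base import (
    MappingResults,
    Standardizer,
    U_MIN_CN,
    UtilityMappingModel,
    cov_from_hessian,
    param_index,
)

__all__ = ["BetaMixtureMapping"]

_EPS = 1e-6  # lower clamp for rescaled non-ceiling values


class BetaMixtureMapping(UtilityMappingModel):
    """One-inflated (optionally truncated) beta mixture mapping model."""

    def __init__(
        self,
        endog,
        exog,
        n_components: int = 1,
        inflate_one: bool = True,
        truncated: bool = False,
        u_min: float = U_MIN_CN,
    ):
        super().__init__(endog, exog)
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)
        self.inflate_one = bool(inflate_one)
        self.truncated = bool(truncated)
        self.u_min = float(u_min)

        y_star = (self.endog - self.u_min) / (1.0 - self.u_min)
        self.at_ceiling = y_star >= 1.0 - 1e-12
        if self.at_ceiling.all():
            raise ValueError("all utilities at full health: continuous part unidentified")
        y_nc = y_star[~self.at_ceiling]
        if np.any(y_nc > 1.0) or np.any(y_nc < -1e-12):
            raise ValueError("utilities outside [u_min, 1] after rescaling")
        # beta support is open at both ends
        self.y_nc = np.clip(y_nc, _EPS, 1.0 - 1e-10)
        self.X_nc = self.exog[~self.at_ceiling]
        self.ceiling_degenerate = self.inflate_one and not self.at_ceiling.any()
        self.tau = float(self.y_nc.max()) if self.truncated else None

        self._log_y = np.log(self.y_nc)
        self._log_1my = np.log1p(-self.y_nc)
        self._has_gamma = self.inflate_one and not self.ceiling_degenerate
        self._std = Standardizer(self.exog)
        self._Xs = self._std.transform(self.exog)
        self._Xs_nc = self._Xs[~self.at_ceiling]

    # -- parameter vector layout --------------------------------------
    # [beta_1 .. beta_C (p each) | log phi_1..C | alpha_2..C | gamma (p)]

    def _split(self, theta: np.ndarray):
        p, C = self.k_exog, self.n_components
        B = theta[: C * p].reshape(C, p)
        logphi = theta[C * p : C * p + C]
        alpha = theta[C * p + C : C * p + C + (C - 1)]
        gamma = theta[-p:] if self._has_gamma else None
        return B, logphi, alpha, gamma

    def _weights(self, alpha: np.ndarray) -> np.ndarray:
        return softmax(np.concatenate(([0.0], alpha)))

    def _component_logpdf(self, B, logphi, X_nc):
        """(n_nc x C) matrix of per-component beta log-densities."""
        eta = X_nc @ B.T
        mu = np.clip(expit(eta), 1e-10, 1.0 - 1e-10)
        phi = np.exp(logphi)
        a = mu * phi
        b = (1.0 - mu) * phi
        logf = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * self._log_y[:, None]
            + (b - 1.0) * self._log_1my[:, None]
        )
        if self.truncated:
            cdf = np.clip(betainc(a, b, self.tau), 1e-300, None)
            logf -= np.log(cdf)
        return logf, mu, phi, a, b

    def _ll(self, theta: np.ndarray, X_nc, X_all) -> float:
        B, logphi, alpha, gamma = self._split(theta)
        pi = self._weights(alpha)
        logf, *_ = self._component_logpdf(B, logphi, X_nc)
        ll = float(logsumexp(logf + np.log(pi), axis=1).sum())
        if self._has_gamma:
            eta_g = X_all @ gamma
            ll += float(log_expit(eta_g[self.at_ceiling]).sum())
            ll += float(log_expit(-eta_g[~self.at_ceiling]).sum())
        return ll

    def _score(self, theta: np.ndarray, X_nc, X_all) -> np.ndarray:
        """Analytic gradient (untruncated model only)."""
        if self.truncated:
            raise NotImplementedError("analytic gradient not available when truncated")
        B, logphi, alpha, gamma = self._split(theta)
        pi = self._weights(alpha)
        logf, mu, phi, a, b = self._component_logpdf(B, logphi, X_nc)
        logw = logf + np.log(pi)
        w = softmax(logw, axis=1)  # responsibilities
        # d log f / d mu, chained through the logit link
        dmu = phi * (-psi(a) + psi(b) + self._log_y[:, None] - self._log_1my[:, None])
        g_beta = (X_nc.T @ (w * dmu * mu * (1.0 - mu))).T.ravel()
        dlogphi = phi * (
            psi(phi)
            - mu * psi(a)
            - (1.0 - mu) * psi(b)
            + mu * self._log_y[:, None]
            + (1.0 - mu) * self._log_1my[:, None]
        )
        g_logphi = (w * dlogphi).sum(axis=0)
        g_alpha = (w - pi).sum(axis=0)[1:]
        grads = [g_beta, g_logphi, g_alpha]
        if self._has_gamma:
            resid = self.at_ceiling.astype(float) - expit(X_all @ gamma)
            grads.append(X_all.T @ resid)
        return np.concatenate(grads)

    def loglike(self, theta: np.ndarray) -> float:
        """Log-likelihood at raw-scale parameters (as reported in results)."""
        return self._ll(theta, self.X_nc, self.exog)

    def score(self, theta: np.ndarray) -> np.ndarray:
        """Gradient at raw-scale parameters (untruncated model only)."""
        return self._score(theta, self.X_nc, self.exog)

    # -- initialization ------------------------------------------------

    def _moment_start(self) -> np.ndarray:
        """Moment-based start in standardized-coefficient space."""
        p, C = self.k_exog, self.n_components
        e = np.log(self.y_nc) - np.log1p(-self.y_nc)  # empirical logit
        b0, *_ = np.linalg.lstsq(self._Xs_nc, e, rcond=None)
        mu_hat = expit(self._Xs_nc @ b0)
        resid_var = max(float(np.var(self.y_nc - mu_hat)), 1e-6)
        mu_bar = float(np.mean(mu_hat))
        phi0 = float(np.clip(mu_bar * (1.0 - mu_bar) / resid_var - 1.0, 2.0, 500.0))
        offsets = np.linspace(-0.8, 0.8, C) if C > 1 else np.zeros(1)
        B = np.tile(b0, (C, 1))
        B[:, 0] += offsets
        theta = [B.ravel(), np.full(C, np.log(phi0)), np.zeros(C - 1)]
        if self._has_gamma:
            frac = float(np.clip(self.at_ceiling.mean(), 1e-4, 1 - 1e-4))
            g = np.zeros(p)
            g[0] = np.log(frac / (1.0 - frac))
            theta.append(g)
        return np.concatenate(theta)

    # -- fit -----------------------------------------------------------

    def fit(
        self,
        n_starts: int = 20,
        tol: float = 1e-8,
        seed: int = 0,
        maxiter: int = 2000,
    ) -> MappingResults:
        p, C = self.k_exog, self.n_components
        start0 = self._moment_start()
        rng = np.random.default_rng(seed)
        n_theta = len(start0)
        lo = np.concatenate(
            [
                np.full(C * p, -40.0),
                np.full(C, np.log(1e-2)),
                np.full(C - 1, -15.0),
                np.full(p, -40.0) if self._has_gamma else [],
            ]
        )
        hi = -lo.copy()
        hi[C * p : C * p + C] = np.log(1e6)
        bounds = list(zip(lo, hi))

        jac = None if self.truncated else (
            lambda t: -self._score(t, self._Xs_nc, self._Xs)
        )
        fun = lambda t: -self._ll(t, self._Xs_nc, self._Xs)
        best = None
        n_used = 0
        for s in range(max(int(n_starts), 1)):
            theta0 = start0 if s == 0 else start0 + rng.normal(0.0, 0.3, n_theta)
            theta0 = np.clip(theta0, lo, hi)
            res = minimize(
                fun,
                theta0,
                jac=jac,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
            )
            n_used += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                "beta mixture failed to converge from any start; "
                f"best objective: {None if best is None else best.fun}"
            )

        theta_std = self._order_components(best.x)
        cov_std = cov_from_hessian(fun, theta_std)
        theta_raw, se_raw = self._to_raw(theta_std, cov_std)
        llf = float(-best.fun)
        return self._pack_results(theta_raw, se_raw, llf, bool(best.success), n_used)

    def _to_raw(self, theta_std: np.ndarray, cov_std: np.ndarray):
        """Map standardized-scale parameters and covariance to raw scores."""
        p, C = self.k_exog, self.n_components
        B, logphi, alpha, gamma = self._split(theta_std)
        M = self._std.M
        blocks = [M] * C + [np.eye(C + (C - 1))]
        parts = [np.array([M @ B[c] for c in range(C)]).ravel(), logphi, alpha]
        if self._has_gamma:
            blocks.append(M)
            parts.append(M @ gamma)
        T = block_diag(*blocks)
        theta_raw = np.concatenate(parts)
        with np.errstate(invalid="ignore"):
            cov_raw = T @ cov_std @ T.T
            d = np.diag(cov_raw)
            se_raw = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        return theta_raw, se_raw

    def _order_components(self, theta: np.ndarray) -> np.ndarray:
        """Relabel components in ascending mean at the covariate mean."""
        if self.n_components == 1:
            return theta
        B, logphi, alpha, gamma = self._split(theta)
        xbar = self._Xs_nc.mean(axis=0)
        order = np.argsort(B @ xbar)
        pi = self._weights(alpha)[order]
        new_alpha = np.log(pi[1:]) - np.log(pi[0])
        parts = [B[order].ravel(), logphi[order], new_alpha]
        if gamma is not None:
            parts.append(gamma)
        return np.concatenate(parts)

    def _pack_results(self, theta, se, llf, success, n_used) -> MappingResults:
        p, C = self.k_exog, self.n_components
        B, logphi, alpha, gamma = self._split(theta)
        phi = np.exp(logphi)
        pi = self._weights(alpha)
        se_B = se[: C * p].reshape(C, p)
        se_logphi = se[C * p : C * p + C]
        se_pi = self._pi_se(alpha, se[C * p + C : C * p + C + (C - 1)])

        entries, values, ses = [], [], []
        for c in range(C):
            for j, name in enumerate(self.exog_names):
                entries.append(("mean", c + 1, name))
                values.append(B[c, j])
                ses.append(se_B[c, j])
        for c in range(C):
            entries.append(("precision", c + 1, "phi"))
            values.append(phi[c])
            ses.append(phi[c] * se_logphi[c])  # delta method
        for c in range(C):
            entries.append(("weight", c + 1, "pi"))
            values.append(pi[c])
            ses.append(se_pi[c])
        if self.inflate_one:
            if self.ceiling_degenerate:
                g = np.zeros(p)
                g[0] = -np.inf
                gse = np.full(p, np.nan)
            else:
                g, gse = gamma, se[-p:]
            for j, name in enumerate(self.exog_names):
                entries.append(("ceiling", 1, name))
                values.append(g[j])
                ses.append(gse[j])

        k = C * p + C + (C - 1) + (p if self._has_gamma else 0)
        return MappingResults(
            family="BETA",
            params=pd.Series(values, index=param_index(entries)),
            bse=pd.Series(ses, index=param_index(entries)),
            llf=float(llf),
            k_params=k,
            nobs=self.nobs,
            exog_names=self.exog_names,
            converged=success,
            n_starts_used=n_used,
            options={
                "u_min": self.u_min,
                "n_components": C,
                "inflate_one": self.inflate_one,
                "truncated": self.truncated,
                "tau": self.tau,
                "ceiling_degenerate": self.ceiling_degenerate,
            },
        )

    def _pi_se(self, alpha: np.ndarray, se_alpha: np.ndarray) -> np.ndarray:
        """Delta-method SEs for the mixture weights (diagonal alpha cov)."""
        C = self.n_components
        if C == 1:
            return np.array([0.0])
        pi = self._weights(alpha)
        if not np.all(np.isfinite(se_alpha)):
            return np.full(C, np.nan)
        J = np.zeros((C, C - 1))
        for i in range(C):
            for j in range(C - 1):
                J[i, j] = pi[i] * ((1.0 if i == j + 1 else 0.0) - pi[j + 1])
        var = J @ np.diag(se_alpha**2) @ J.T
        return np.sqrt(np.clip(np.diag(var), 0.0, None))
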