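"""Shared Model / Results machinery for the four mapping families."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = ["MappingResults", "UtilityMappingModel", "param_index"]

U_MIN_CN = -0.391  # lower bound of the Chinese EQ-5D-5L TTO tariff


def param_index(entries: list[tuple[str, int, str]]) -> pd.MultiIndex:
    """(part, component, name) index for parameter vectors.

    Parts: ``mean`` (regression coefficients, per mixture component; the only
    part for OLS/Tobit; part 2 of the two-part model), ``ceiling`` (logistic
    coefficients for P(utility = 1)), ``scale`` (Gaussian sigma),
    ``precision`` (beta phi_c) and ``weight`` (mixture pi_c).
    """
    return pd.MultiIndex.from_tuples(entries, names=["part", "component", "name"])


def _check_design(X: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("design matrix must be a pandas DataFrame with named columns")
    if X.shape[1] < 1 or X.columns[0] != "intercept":
        raise ValueError("design matrix must carry a leading 'intercept' column")
    return X


def find_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Names of columns involved in a rank deficiency (via QR pivoting)."""
    _, r, piv = _qr_pivot(X)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return []
    bad = diag < tol * max(diag[0], 1.0)
    return [names[piv[i]] for i in np.flatnonzero(bad)]


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


@dataclass
class MappingResults:
    """Fit results with a uniform predict / criteria / summary contract.

    ``params`` and ``bse`` are indexed by (part, component, name); ``llf`` is
    the maximized log-likelihood, ``k_params`` the number of freely estimated
    parameters entering AIC/BIC (sigma counted for OLS/Tobit; both parts for
    the two-part model; means + precisions + C-1 weights + ceiling
    coefficients for the beta mixture).
    """

    family: str
    params: pd.Series
    bse: pd.Series
    llf: float
    k_params: int
    nobs: int
    exog_names: list[str]
    converged: bool = True
    n_starts_used: int = 1
    options: dict[str, Any] = field(default_factory=dict)
    cov_params: pd.DataFrame | None = None

    # -- information criteria -----------------------------------------

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.nobs) - 2.0 * self.llf

    # -- inference ----------------------------------------------------

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values against a standard normal reference."""
        return pd.Series(
            2.0 * norm.sf(np.abs(self.tvalues.to_numpy(dtype=float))),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    # -- parameter access ---------------------------------------------

    def part_params(self, part: str, component: int = 1) -> np.ndarray:
        sub = self.params.xs((part, component), level=("part", "component"))
        return sub.reindex(self.exog_names).to_numpy(dtype=float)

    def scalar(self, part: str, component: int, name: str) -> float:
        return float(self.params.loc[(part, component, name)])

    @property
    def n_components(self) -> int:
        return int(self.options.get("n_components", 1))

    @property
    def mixture_weights(self) -> np.ndarray:
        if ("weight", 1, "pi") not in self.params.index:
            return np.array([1.0])
        return np.array(
            [self.scalar("weight", c, "pi") for c in range(1, self.n_components + 1)]
        )

    # -- prediction ----------------------------------------------------

    def _exog_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.exog_names if c not in X.columns]
            if missing:
                raise KeyError(f"design matrix is missing columns {missing}")
            return X[self.exog_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.exog_names):
            raise ValueError(
                f"design has {X.shape[1]} columns, fit expects {len(self.exog_names)}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Predicted utility per family convention.

        OLS: x'b.  Tobit: the latent index x'b (uncensored; may exceed 1).
        Two-part: L(g'x) * 1 + (1 - L(g'x)) * x'b.  Beta mixture:
        u_min + (1 - u_min) * [L + (1 - L) * sum_c pi_c mu_c(x)], with the
        truncated-beta mean substituted when the fit was truncated.
        """
        A = self._exog_array(X)
        if self.family in ("OLS", "TOBIT"):
            return A @ self.part_params("mean")
        if self.family == "TPM":
            mean = A @ self.part_params("mean")
            if self.options.get("ceiling_degenerate", False):
                return mean
            lam = expit(A @ self.part_params("ceiling"))
            return lam + (1.0 - lam) * mean
        if self.family == "BETA":
            return self._predict_beta(A)
        raise ValueError(f"unknown family {self.family!r}")

    def _predict_beta(self, A: np.ndarray) -> np.ndarray:
        from scipy.special import betainc

        u_min = float(self.options.get("u_min", U_MIN_CN))
        C = self.n_components
        pis = self.mixture_weights
        tau = self.options.get("tau")
        mean_star = np.zeros(A.shape[0])
        for c in range(1, C + 1):
            mu = expit(A @ self.part_params("mean", c))
            if self.options.get("truncated", False) and tau is not None:
                phi = self.scalar("precision", c, "phi")
                a, b = mu * phi, (1.0 - mu) * phi
                mu = mu * betainc(a + 1.0, b, tau) / betainc(a, b, tau)
            mean_star += pis[c - 1] * mu
        if self.options.get("inflate_one", False) and not self.options.get(
            "ceiling_degenerate", False
        ):
            lam = expit(A @ self.part_params("ceiling"))
            mean_star = lam + (1.0 - lam) * mean_star
        return u_min + (1.0 - u_min) * mean_star

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"{self.family} utility mapping results",
            "=" * 64,
            f"No. observations: {self.nobs:>8d}    Log-likelihood: {self.llf:12.4f}",
            f"No. parameters:   {self.k_params:>8d}    AIC: {self.aic:12.3f}   BIC: {self.bic:12.3f}",
            f"Converged: {str(self.converged):>5s}    starts used: {self.n_starts_used}",
            "-" * 64,
            f"{'part':<10}{'comp':>4} {'name':<14}{'coef':>12}{'std err':>10}{'P>|z|':>9}",
            "-" * 64,
        ]
        pv = self.pvalues
        for key in self.params.index:
            part, comp, name = key
            se = self.bse.loc[key]
            se_s = f"{se:>10.4f}" if np.isfinite(se) else f"{'--':>10}"
            p_s = f"{pv.loc[key]:>9.4f}" if np.isfinite(pv.loc[key]) else f"{'--':>9}"
            lines.append(
                f"{part:<10}{comp:>4} {name:<14}{self.params.loc[key]:>12.5f}{se_s}{p_s}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        from .io import results_to_csv

        results_to_csv(self, path)


class UtilityMappingModel:
    """Base class: holds endog (utility) and exog (design with intercept)."""

    def __init__(self, endog, exog: pd.DataFrame):
        self.exog_frame = _check_design(exog)
        self.exog = self.exog_frame.to_numpy(dtype=float)
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        self.exog_names = list(self.exog_frame.columns)
        self.nobs, self.k_exog = self.exog.shape

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, spec: int, screened=None, **kwargs):
        """Construct from a cohort table and a covariate specification id."""
        from ..scoring import build_design

        X = build_design(cohort, spec, screened)
        return cls(cohort["utility"].to_numpy(dtype=float), X, **kwargs)

    def fit(self, **kwargs) -> MappingResults:  # pragma: no cover - abstract
        raise NotImplementedError


class Standardizer:
    """Internal column standardization for optimizer conditioning.

    Fits run on ``(X - m) / s`` (intercept untouched); coefficient vectors
    and their covariance blocks are mapped back to the raw scale, so the
    external contract (raw-score coefficients) is unchanged.
    """

    def __init__(self, X: np.ndarray):
        self.m = X.mean(axis=0)
        self.s = X.std(axis=0)
        self.m[0] = 0.0
        self.s[0] = 1.0
        self.s[self.s == 0] = 1.0
        p = X.shape[1]
        M = np.zeros((p, p))
        M[0, 0] = 1.0
        for j in range(1, p):
            M[j, j] = 1.0 / self.s[j]
            M[0, j] = -self.m[j] / self.s[j]
        self.M = M  # beta_raw = M @ beta_std

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.m) / self.s

    def raw_coef(self, b_std: np.ndarray) -> np.ndarray:
        return self.M @ b_std

    def std_coef(self, b_raw: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.M, b_raw)

    def raw_cov_block(self, cov_std: np.ndarray) -> np.ndarray:
        return self.M @ cov_std @ self.M.T


def cov_from_hessian(neg_loglike, theta: np.ndarray) -> np.ndarray:
    """Covariance matrix from the numerical Hessian of -loglik (NaN on failure)."""
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta, neg_loglike)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((len(theta), len(theta)), np.nan)


def se_from_hessian(neg_loglike, theta: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the numerical Hessian of -loglik."""
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta, neg_loglike)
    se = np.full(len(theta), np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        ok = d > 0
        se[ok] = np.sqrt(d[ok])
    except np.linalg.LinAlgError:
        pass
    return se
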