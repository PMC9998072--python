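"""Mapping estimators: OLS, right-censored Tobit, two-part and one-inflated
beta mixture models with a uniform fit/predict contract.

Model classes follow the statsmodels idiom (``Model(endog, exog).fit()``
returns a :class:`MappingResults`); the module-level ``fit_*`` helpers wrap
them for pipeline use.
"""

from __future__ import annotations

import numpy as np

from .base import MappingResults, U_MIN_CN, UtilityMappingModel
from .beta import BetaMixtureMapping
from .io import results_from_csv, results_to_csv
from .linear import OLSMapping, TobitMapping
from .two_part import TwoPartMapping

__all__ = [
    "MappingResults",
    "UtilityMappingModel",
    "OLSMapping",
    "TobitMapping",
    "TwoPartMapping",
    "BetaMixtureMapping",
    "fit_ols",
    "fit_tobit",
    "fit_two_part",
    "fit_beta_mixture",
    "fit_model_family",
    "predict",
    "results_to_csv",
    "results_from_csv",
    "U_MIN_CN",
]


def fit_ols(X, y) -> MappingResults:
    return OLSMapping(y, X).fit()


def fit_tobit(X, y, upper: float = 1.0) -> MappingResults:
    return TobitMapping(y, X, upper=upper).fit()


def fit_two_part(X, y, ceiling: float = 1.0) -> MappingResults:
    return TwoPartMapping(y, X, ceiling=ceiling).fit()


def fit_beta_mixture(
    X,
    y,
    components: int = 1,
    inflate_one: bool = True,
    truncated: bool = False,
    u_min: float = U_MIN_CN,
    n_starts: int = 20,
    tol: float = 1e-8,
    seed: int = 0,
) -> MappingResults:
    model = BetaMixtureMapping(
        y,
        X,
        n_components=components,
        inflate_one=inflate_one,
        truncated=truncated,
        u_min=u_min,
    )
    return model.fit(n_starts=n_starts, tol=tol, seed=seed)


def fit_model_family(family: str, X, y, **kwargs) -> MappingResults:
    """Dispatch a fit by family name (OLS / TOBIT / TPM / BETA)."""
    family = family.upper()
    if family == "OLS":
        return fit_ols(X, y)
    if family == "TOBIT":
        return fit_tobit(X, y, **kwargs)
    if family == "TPM":
        return fit_two_part(X, y, **kwargs)
    if family == "BETA":
        return fit_beta_mixture(X, y, **kwargs)
    raise ValueError(f"unknown estimator family {family!r}")


def predict(fit: MappingResults, X) -> np.ndarray:
    """Functional alias for :meth:`MappingResults.predict`."""
    return fit.predict(X)
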