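"""Two-part model: logistic ceiling probability + OLS below the ceiling.

Part 1 is a logistic regression of the full-health indicator 1{y = ceiling};
part 2 is OLS fitted on the non-ceiling subjects only.  Predictions mix the
two parts; the reported log-likelihood (entering AIC/BIC) is the sum of both
parts' log-likelihoods and k counts both coefficient vectors plus sigma.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import MappingResults, UtilityMappingModel, param_index

__all__ = ["TwoPartMapping"]


class TwoPartMapping(UtilityMappingModel):
    def __init__(self, endog, exog, ceiling: float = 1.0):
        super().__init__(endog, exog)
        self.ceiling = float(ceiling)
        self.at_ceiling = self.endog >= self.ceiling

    def fit(self) -> MappingResults:
        import statsmodels.api as sm

        if self.at_ceiling.all():
            raise ValueError("all observations at the ceiling: part 2 unidentified")
        n_ceiling = int(self.at_ceiling.sum())
        degenerate = n_ceiling == 0

        # part 2: OLS on the non-ceiling subjects
        mask = ~self.at_ceiling
        ols = sm.OLS(self.endog[mask], self.exog[mask]).fit()
        sigma = float(np.sqrt(np.mean(ols.resid**2)))
        llf2 = float(ols.llf)

        entries = [("mean", 1, n) for n in self.exog_names] + [("scale", 1, "sigma")]
        values = list(ols.params) + [sigma]
        ses = list(ols.bse) + [sigma / np.sqrt(2.0 * mask.sum())]

        if degenerate:
            # gamma = -inf convention: ceiling probability identically 0
            gamma = np.full(self.k_exog, 0.0)
            gamma[0] = -np.inf
            gamma_se = np.full(self.k_exog, np.nan)
            llf1 = 0.0
            converged = True
        else:
            logit = sm.Logit(self.at_ceiling.astype(float), self.exog)
            lres = logit.fit(disp=0, maxiter=200)
            gamma, gamma_se = np.asarray(lres.params), np.asarray(lres.bse)
            llf1 = float(lres.llf)
            converged = bool(lres.mle_retvals.get("converged", True))
        entries += [("ceiling", 1, n) for n in self.exog_names]
        values += list(gamma)
        ses += list(gamma_se)

        idx = param_index(entries)
        return MappingResults(
            family="TPM",
            params=pd.Series(values, index=idx),
            bse=pd.Series(ses, index=idx),
            llf=llf1 + llf2,
            k_params=2 * self.k_exog + 1,
            nobs=self.nobs,
            exog_names=self.exog_names,
            converged=converged,
            options={"ceiling": self.ceiling, "ceiling_degenerate": degenerate},
        )
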