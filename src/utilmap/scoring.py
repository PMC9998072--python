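"""Instrument scoring and covariate specifications.

The FACT-H&N carries five subscales — Physical (PWB, 0-28), Social/Family
(SWB, 0-28), Emotional (EWB, 0-24), Functional Well-being (FWB, 0-28) and the
Head & Neck Cancer Subscale (HNCS, 0-40) — summing to a total of 0-148.
Six covariate specifications are used by every mapping family:

1. intercept + total score
2. intercept + the five subscales
3. intercept + the screened ("meaningful", Wald P < 0.01 in spec 2) subscales
4. spec 3 + squares of the screened subscales (suffix ``_sq``)
5. spec 4 + pairwise interactions of the screened subscales (``a_x_b``)
6. spec 5 + age + gender (1 = female)
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import DEFAULT_SUBSCALE_RANGES, SUBSCALES

__all__ = [
    "total_score",
    "screen_subscales",
    "build_design",
    "spec_columns",
    "DEFAULT_SCREENED",
]

#: The screened subscale set published for spec 3 and shared by all families.
DEFAULT_SCREENED = ("pwb", "ewb", "hncs")

TOTAL_MAX = 148


def total_score(
    pwb: int, swb: int, ewb: int, fwb: int, hncs: int, *, validate: bool = True
) -> int:
    """Sum of the five subscale scores, in [0, 148] under default ranges."""
    scores = {"pwb": pwb, "swb": swb, "ewb": ewb, "fwb": fwb, "hncs": hncs}
    if validate:
        for name, value in scores.items():
            lo, hi = DEFAULT_SUBSCALE_RANGES[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{name} score {value} outside instrument range [{lo}, {hi}]"
                )
    return int(sum(scores.values()))


def spec_columns(spec: int, screened: tuple[str, ...] = DEFAULT_SCREENED) -> list[str]:
    """Ordered design-matrix column names for covariate specification 1-6."""
    if spec not in range(1, 7):
        raise ValueError(f"unknown covariate specification id {spec!r} (must be 1-6)")
    if spec == 1:
        return ["intercept", "total"]
    if spec == 2:
        return ["intercept", *SUBSCALES]
    screened = tuple(s for s in SUBSCALES if s in screened)  # canonical order
    if not screened:
        raise ValueError("screened subscale set must be non-empty for specs 3-6")
    cols = ["intercept", *screened]
    if spec >= 4:
        cols += [f"{s}_sq" for s in screened]
    if spec >= 5:
        cols += [f"{a}_x_{b}" for a, b in combinations(screened, 2)]
    if spec == 6:
        cols += ["age", "gender"]
    return cols


def build_design(
    cohort: pd.DataFrame,
    spec: int,
    screened: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Build the n x p design matrix (leading intercept) for a specification.

    Pure function of (cohort, spec, screened): the same inputs always produce
    an identical matrix with a deterministic column order.
    """
    if screened is None:
        screened = DEFAULT_SCREENED
    cols = spec_columns(spec, tuple(screened))
    data: dict[str, np.ndarray] = {}
    for name in cols:
        if name == "intercept":
            data[name] = np.ones(len(cohort))
        elif name.endswith("_sq"):
            data[name] = cohort[name[:-3]].to_numpy(dtype=float) ** 2
        elif "_x_" in name:
            a, b = name.split("_x_", 1)
            data[name] = cohort[a].to_numpy(dtype=float) * cohort[b].to_numpy(dtype=float)
        else:
            if name not in cohort.columns:
                raise KeyError(f"cohort is missing required column {name!r}")
            data[name] = cohort[name].to_numpy(dtype=float)
    return pd.DataFrame(data, columns=cols, index=cohort.index)


def screen_subscales(
    cohort: pd.DataFrame,
    family: str = "OLS",
    alpha: float = 0.01,
    **fit_kwargs,
) -> tuple[str, ...]:
    """Subscales whose spec-2 coefficient is significant at ``alpha``.

    Fits the five-subscale specification with the requested estimator family
    and applies a two-sided Wald test (coefficient / asymptotic SE against a
    standard normal) to each subscale coefficient.  For the two-part model a
    subscale counts as significant if it is significant in either part; for
    the beta mixture the single-component mean model is screened.
    """
    from .models import fit_model_family

    X = build_design(cohort, spec=2)
    y = cohort["utility"].to_numpy(dtype=float)
    res = fit_model_family(family, X, y, **fit_kwargs)
    pvals = res.pvalues
    out = []
    for s in SUBSCALES:
        ps = [p for (part, comp, name), p in pvals.items() if name == s and np.isfinite(p)]
        if ps and min(ps) < alpha:
            out.append(s)
    return tuple(out)
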