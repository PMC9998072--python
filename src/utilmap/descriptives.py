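"""Cohort descriptives: Spearman correlation screen, strength bands,
composition tables and ceiling/floor proportions.

A mapping function is only worth fitting when the source and target
instruments correlate; Spearman's rank correlation (mid-ranks for ties) is
the standard screen, read against the conventional strength bands
0-0.19 very weak, 0.2-0.39 weak, 0.40-0.59 moderate, 0.6-0.79 strong,
0.8-1 very strong (applied to |rho|).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SUBSCALES

__all__ = [
    "spearman",
    "strength_band",
    "composition_table",
    "boundary_proportions",
    "correlation_table",
]

_BANDS = [
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.01, "very strong"),
]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (mid-rank ties) and its large-sample t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def strength_band(rho: float) -> str:
    """Conventional label for |rho|; boundary values (0.20, 0.40, 0.60, 0.80)
    belong to the band whose printed range starts there."""
    a = abs(float(rho))
    if a > 1:
        raise ValueError("|rho| cannot exceed 1")
    for cut, label in _BANDS:
        if a < cut:
            return label
    return "very strong"  # pragma: no cover


def composition_table(column) -> pd.DataFrame:
    """Per-level counts and composition ratios (%, 2 decimals)."""
    s = pd.Series(column)
    if s.empty:
        raise ValueError("empty input")
    counts = s.value_counts(sort=False)
    return pd.DataFrame(
        {
            "count": counts,
            "percent": (100.0 * counts / counts.sum()).round(2),
        }
    )


def boundary_proportions(utilities, threshold: float = 0.5) -> tuple[float, float]:
    """(% exactly at full health, % strictly below ``threshold``)."""
    u = np.asarray(utilities, dtype=float)
    if u.size == 0:
        raise ValueError("empty input")
    if np.any(u > 1.0) or np.any(u < -0.391):
        raise ValueError("utilities outside [-0.391, 1]")
    ceiling = 100.0 * float(np.mean(u == 1.0))
    below = 100.0 * float(np.mean(u < threshold))
    return ceiling, below


def correlation_table(cohort: pd.DataFrame, round_to: int = 3) -> pd.DataFrame:
    """Spearman correlations of utility against FACT-H&N subscales + total.

    Two rows per statistic (rho, p).  EQ-5D-5L dimension-level rows are only
    possible when the cohort carries dimension responses, which the synthetic
    generator does not emit.
    """
    cols = [s for s in SUBSCALES if s in cohort.columns] + ["total"]
    rhos, ps = {}, {}
    u = cohort["utility"].to_numpy(dtype=float)
    for c in cols:
        rho, p = spearman(cohort[c].to_numpy(dtype=float), u)
        rhos[c], ps[c] = round(rho, round_to), p
    return pd.DataFrame({"rho": rhos, "p_value": ps})
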