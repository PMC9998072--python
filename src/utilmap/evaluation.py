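"""Goodness-of-fit metrics, fivefold cross-validation and ARV model ranking.

Six indicators are computed per model: MAE, RMSE, AIC (2k - 2ll), BIC
(k ln n - 2ll) and the share of absolute errors exceeding 0.05 and 0.10
(strict inequality, reported in percent).  Smaller is better for all six.
Models are compared by ranking each indicator across models (average ranks
for ties) and averaging the six ranks into the ARV; the lowest ARV wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .specs import ModelSpec, fit_model_spec
from .scoring import build_design

__all__ = [
    "MetricSet",
    "compute_metrics",
    "evaluate_in_sample",
    "crossvalidate",
    "arv_rank",
    "summarize_predictions",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ["mae", "rmse", "aic", "bic", "ae_gt_005", "ae_gt_010"]


@dataclass(frozen=True)
class MetricSet:
    mae: float
    rmse: float
    aic: float
    bic: float
    ae_gt_005: float  # percentage of |error| > 0.05
    ae_gt_010: float  # percentage of |error| > 0.10

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.mae, self.rmse, self.aic, self.bic, self.ae_gt_005, self.ae_gt_010],
            index=METRIC_COLUMNS,
        )


def compute_metrics(
    observed, predicted, loglik: float, k: int, n: int
) -> MetricSet:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    if n < 1:
        raise ValueError("n must be >= 1")
    err = np.abs(observed - predicted)
    return MetricSet(
        mae=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        aic=2.0 * k - 2.0 * loglik,
        bic=k * np.log(n) - 2.0 * loglik,
        ae_gt_005=100.0 * float(np.mean(err > 0.05)),
        ae_gt_010=100.0 * float(np.mean(err > 0.10)),
    )


def _metric_row(ms: MetricSet, status: str = "ok", **extra) -> dict:
    row = {c: getattr(ms, c) for c in METRIC_COLUMNS}
    row["status"] = status
    row.update(extra)
    return row


def evaluate_in_sample(
    cohort: pd.DataFrame, specs: list[ModelSpec], seed: int = 0
) -> pd.DataFrame:
    """Fit each model on the full cohort and score it on the same data."""
    y = cohort["utility"].to_numpy(dtype=float)
    rows = {}
    for spec in specs:
        try:
            fit = fit_model_spec(cohort, spec, seed=seed)
            X = build_design(cohort, spec.spec_id, spec.screened)
            ms = compute_metrics(y, fit.predict(X), fit.llf, fit.k_params, fit.nobs)
            rows[spec.label] = _metric_row(ms)
        except Exception as exc:  # a failed model must not sink the grid
            rows[spec.label] = {c: np.nan for c in METRIC_COLUMNS} | {
                "status": f"failed: {exc}"
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def crossvalidate(
    cohort: pd.DataFrame,
    specs: list[ModelSpec],
    folds: int = 5,
    seed: int = 0,
    repeated_splits: bool = False,
) -> pd.DataFrame:
    """Cross-validated metrics per model.

    Default mode is a seeded k-fold partition: every row serves exactly once
    in a validation fold (~20% of the sample for k = 5) and the error metrics
    are averaged over folds; AIC/BIC are averaged over the k training fits.
    ``repeated_splits`` instead draws ``folds`` independent random 80/20
    splits (a repeated hold-out reading of the same protocol).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    from sklearn.model_selection import KFold, ShuffleSplit

    y_all = cohort["utility"].to_numpy(dtype=float)
    if repeated_splits:
        splitter = ShuffleSplit(n_splits=folds, test_size=0.2, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    split_indices = list(splitter.split(np.arange(len(cohort))))

    rows = {}
    for spec in specs:
        fold_metrics = []
        failed = None
        for train_idx, test_idx in split_indices:
            train = cohort.iloc[train_idx]
            test = cohort.iloc[test_idx]
            try:
                fit = fit_model_spec(train, spec, seed=seed)
            except Exception as exc:
                failed = exc
                break
            X_test = build_design(test, spec.spec_id, spec.screened)
            pred = fit.predict(X_test)
            fold_metrics.append(
                compute_metrics(y_all[test_idx], pred, fit.llf, fit.k_params, fit.nobs)
            )
        if failed is not None:
            rows[spec.label] = {c: np.nan for c in METRIC_COLUMNS} | {
                "status": f"failed: {failed}"
            }
            continue
        agg = {c: float(np.mean([getattr(m, c) for m in fold_metrics])) for c in METRIC_COLUMNS}
        agg["status"] = "ok"
        rows[spec.label] = agg
    return pd.DataFrame.from_dict(rows, orient="index")


def arv_rank(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average-rank-value table; lowest ARV is the preferred model.

    Each of the six metric columns is ranked ascending across models (all six
    are better-smaller; AIC/BIC are signed, so more negative ranks better)
    with average ranks for ties.  Rows are sorted by ARV, ties broken by
    model name for determinism.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two models to rank")
    usable = metrics
    for col in METRIC_COLUMNS:
        if col not in metrics.columns:
            raise ValueError(f"metric column {col!r} missing")
        bad = metrics.index[metrics[col].isna()]
        if len(bad):
            raise ValueError(f"model {bad[0]!r} is missing metric {col!r}")
    ranks = pd.DataFrame(
        {col: rankdata(usable[col].to_numpy(), method="average") for col in METRIC_COLUMNS},
        index=usable.index,
    )
    ranks.columns = [f"rank_{c}" for c in METRIC_COLUMNS]
    ranks["arv"] = ranks.mean(axis=1)
    ranks = ranks.sort_values(["arv"]).sort_index(kind="stable").sort_values(
        "arv", kind="stable"
    )
    return ranks


def summarize_predictions(predicted) -> pd.Series:
    """Mean/SD/min/percentile summary plus the share of predictions above 1.

    Percentiles use linear interpolation between order statistics.
    """
    p = np.asarray(predicted, dtype=float)
    if p.size == 0:
        raise ValueError("empty prediction vector")
    q10, q50, q90 = np.percentile(p, [10, 50, 90])
    return pd.Series(
        {
            "mean": float(p.mean()),
            "sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
            "min": float(p.min()),
            "p10": float(q10),
            "p50": float(q50),
            "p90": float(q90),
            "max": float(p.max()),
            "upper_bound_pct": 100.0 * float(np.mean(p > 1.0)),
        }
    )
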