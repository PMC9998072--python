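"""Synthetic cohort generator for utility-mapping studies.

Emulates a head-and-neck cancer quality-of-life survey: five bounded
integer FACT-H&N subscale scores (PWB, SWB, EWB, FWB, HNCS), demographics,
and an EQ-5D-5L utility on the Chinese time-trade-off tariff scale
[-0.391, 1].  Utilities follow a one-inflated beta-mixture data-generating
process: a logistic model puts an exact atom at 1 (full health); below the
ceiling the rescaled utility is drawn from a mixture of beta distributions
whose component means depend on the subscale scores through a logit link.
This is exactly the likelihood the :class:`~utilmap.models.BetaMixtureMapping`
estimator maximizes, so parameter recovery is testable end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "generate_subscales",
    "generate_utilities",
    "make_cohort",
    "SUBSCALES",
    "DEFAULT_SUBSCALE_RANGES",
]

SUBSCALES = ("pwb", "swb", "ewb", "fwb", "hncs")

#: Instrument score ranges; totals span 0-148 (28+28+24+28+40).
DEFAULT_SUBSCALE_RANGES = {
    "pwb": (0, 28),
    "swb": (0, 28),
    "ewb": (0, 24),
    "fwb": (0, 28),
    "hncs": (0, 40),
}

# Latent-score calibration: per-subscale means chosen so the total averages
# ~108 with EWB relatively highest and FWB lowest, matching the survey
# population the generator emulates.
_DEFAULT_MEANS = {"pwb": 23.0, "swb": 21.0, "ewb": 20.0, "fwb": 18.0, "hncs": 26.0}
_DEFAULT_SDS = {"pwb": 4.0, "swb": 4.5, "ewb": 3.5, "fwb": 4.5, "hncs": 5.5}


def _expand_centered_quadratic(
    linear: dict[str, float],
    quadratic: dict[str, float],
    interactions: dict[tuple[str, str], float],
    centers: dict[str, float],
    intercept: float,
) -> dict[str, float]:
    """Expand a quadratic written around covariate centers into raw-score
    coefficients (names ``x``, ``x_sq``, ``x_x_y``)."""
    out: dict[str, float] = {"intercept": intercept}
    for name, b in linear.items():
        c = centers[name]
        out["intercept"] -= b * c
        out[name] = out.get(name, 0.0) + b
    for name, q in quadratic.items():
        c = centers[name]
        out["intercept"] += q * c * c
        out[name] = out.get(name, 0.0) - 2.0 * q * c
        out[f"{name}_sq"] = out.get(f"{name}_sq", 0.0) + q
    for (a, b), w in interactions.items():
        ca, cb = centers[a], centers[b]
        out["intercept"] += w * ca * cb
        out[a] = out.get(a, 0.0) - w * cb
        out[b] = out.get(b, 0.0) - w * ca
        out[f"{a}_x_{b}"] = out.get(f"{a}_x_{b}", 0.0) + w
    return out


def _default_mean_coefficients() -> list[dict[str, float]]:
    """True logit-mean coefficients of the two beta components.

    The dominant component sits near utility 0.9; the minority component
    captures the lower tail.  Curvature and interaction terms are mild but
    nonzero, so quadratic/interaction covariate specifications are the
    well-specified ones.
    """
    centers = {"pwb": 23.0, "ewb": 20.0, "hncs": 26.0}
    base = dict(
        linear={"pwb": 0.0585, "ewb": 0.065, "hncs": 0.039},
        quadratic={"pwb": -0.0015, "ewb": -0.0012, "hncs": -0.0008},
        interactions={
            ("pwb", "ewb"): 0.0008,
            ("pwb", "hncs"): 0.0005,
            ("ewb", "hncs"): 0.0005,
        },
        centers=centers,
    )
    return [
        _expand_centered_quadratic(**base, intercept=2.55),
        _expand_centered_quadratic(**base, intercept=1.45),
    ]


def _default_ceiling_coefficients() -> dict[str, float]:
    # Mean linear predictor ~= logit(0.095) at the covariate means, so just
    # under 10% of subjects report full health.
    return {"intercept": -5.95, "pwb": 0.05, "ewb": 0.06, "hncs": 0.05}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic data-generating process.

    Defaults are calibrated to the survey the generator emulates: n = 1,050
    papillary thyroid carcinoma patients, 76% female, FACT-H&N total
    ~108 +/- 15, mean utility ~0.87 with a ~9.6% ceiling at 1.
    """

    n_subjects: int = 1050
    seed: int = 20230223
    subscale_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSCALE_RANGES)
    )
    subscale_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    subscale_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    subscale_correlation: float = 0.45
    ceiling_coefficients: dict[str, float] = field(
        default_factory=_default_ceiling_coefficients
    )
    component_count: int = 2
    mixture_weights: tuple[float, ...] = (0.90, 0.10)
    mean_coefficients: list[dict[str, float]] = field(
        default_factory=_default_mean_coefficients
    )
    precisions: tuple[float, ...] = (110.0, 28.0)
    u_min: float = -0.391
    age_range: tuple[int, int] = (18, 80)
    female_fraction: float = 0.76

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        for name, (lo, hi) in self.subscale_ranges.items():
            if lo > hi:
                raise ValueError(f"subscale range for {name!r} has min > max")
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != self.component_count:
            raise ValueError("mixture_weights length must equal component_count")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture_weights must be positive and sum to 1")
        if len(self.mean_coefficients) != self.component_count:
            raise ValueError("mean_coefficients length must equal component_count")
        if len(self.precisions) != self.component_count:
            raise ValueError("precisions length must equal component_count")
        if np.any(np.asarray(self.precisions) <= 0):
            raise ValueError("precisions must be positive")
        if self.u_min >= 1:
            raise ValueError("u_min must be < 1")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subscale_ranges"] = {k: list(v) for k, v in d["subscale_ranges"].items()}
        for key in ("mixture_weights", "precisions", "age_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "subscale_ranges" in d:
            d["subscale_ranges"] = {k: tuple(v) for k, v in d["subscale_ranges"].items()}
        for key in ("mixture_weights", "precisions", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """One root seed, deterministic named sub-streams."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    names = ("subscales", "utility", "age", "gender")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_subscales(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the five subscale scores for ``config.n_subjects`` subjects.

    Scores come from a correlated latent multivariate normal (exchangeable
    correlation), rounded to integers and clipped to each subscale's range;
    ``total`` is their sum.
    """
    if rng is None:
        rng = _rngs(config)["subscales"]
    names = [s for s in SUBSCALES if s in config.subscale_ranges]
    k = len(names)
    mu = np.array([config.subscale_means[s] for s in names])
    sd = np.array([config.subscale_sds[s] for s in names])
    rho = config.subscale_correlation
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd, sd)
    latent = rng.multivariate_normal(mu, cov, size=config.n_subjects, method="cholesky")
    scores = np.rint(latent).astype(int)
    for j, s in enumerate(names):
        lo, hi = config.subscale_ranges[s]
        scores[:, j] = np.clip(scores[:, j], lo, hi)
    df = pd.DataFrame(scores, columns=names)
    df.insert(0, "id", np.arange(1, config.n_subjects + 1))
    df["total"] = df[names].sum(axis=1)
    return df


def _covariate_matrix(cohort: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Assemble columns named by coefficient keys; squares (``x_sq``) and
    interactions (``a_x_b``) are derived from the base columns on demand."""
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(len(cohort)))
        elif name in cohort.columns:
            cols.append(cohort[name].to_numpy(dtype=float))
        elif name.endswith("_sq") and name[:-3] in cohort.columns:
            cols.append(cohort[name[:-3]].to_numpy(dtype=float) ** 2)
        elif "_x_" in name:
            a, b = name.split("_x_", 1)
            if a not in cohort.columns or b not in cohort.columns:
                raise KeyError(f"covariate {name!r} not derivable from cohort columns")
            cols.append(
                cohort[a].to_numpy(dtype=float) * cohort[b].to_numpy(dtype=float)
            )
        else:
            raise KeyError(f"covariate {name!r} missing from cohort")
    return np.column_stack(cols)


def _linear_predictor(cohort: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    names = list(coefficients)
    X = _covariate_matrix(cohort, names)
    beta = np.array([coefficients[n] for n in names])
    return X @ beta


def generate_utilities(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one utility per subject from the one-inflated beta mixture.

    With probability ``expit(gamma'x)`` the utility is exactly 1 (the ceiling
    atom is assigned before the continuous draw, so the count of 1s is
    binomial); otherwise ``u = u_min + (1 - u_min) * b`` with ``b`` drawn from
    mixture component c ~ Categorical(pi), b ~ Beta(mu_c * phi_c,
    (1 - mu_c) * phi_c) and ``logit(mu_c) = beta_c'x``.
    """
    if rng is None:
        rng = _rngs(config)["utility"]
    n = len(cohort)
    from scipy.special import expit

    eta_ceiling = _linear_predictor(cohort, config.ceiling_coefficients)
    at_ceiling = rng.random(n) < expit(eta_ceiling)

    comp = rng.choice(config.component_count, size=n, p=np.asarray(config.mixture_weights))
    mu = np.empty(n)
    for c in range(config.component_count):
        mask = comp == c
        if mask.any():
            mu[mask] = expit(_linear_predictor(cohort[mask], config.mean_coefficients[c]))
    phi = np.asarray(config.precisions)[comp]
    b = rng.beta(mu * phi, (1.0 - mu) * phi)
    utility = config.u_min + (1.0 - config.u_min) * b
    utility[at_ceiling] = 1.0
    return utility


def make_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Full cohort table: id, the five subscales, total, age, gender, utility.

    Gender is coded 1 = female.  A fixed seed reproduces the table exactly.
    """
    if config is None:
        config = GeneratorConfig()
    rngs = _rngs(config)
    cohort = generate_subscales(config, rngs["subscales"])
    lo, hi = config.age_range
    cohort["age"] = rngs["age"].integers(lo, hi + 1, size=len(cohort))
    cohort["gender"] = (rngs["gender"].random(len(cohort)) < config.female_fraction).astype(int)
    cohort["utility"] = generate_utilities(cohort, config, rngs["utility"])
    return cohort
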