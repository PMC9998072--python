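"""Synthetic-cohort generator: ranges, determinism, calibrated moments."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from utilmap import GeneratorConfig, generate_subscales, generate_utilities, make_cohort
from utilmap.cohort import SUBSCALES


def test_degenerate_ranges_give_zero_totals():
    cfg = GeneratorConfig(
        n_subjects=25,
        subscale_ranges={s: (0, 0) for s in SUBSCALES},
    )
    table = generate_subscales(cfg)
    assert (table["total"] == 0).all()
    assert (table[list(SUBSCALES)] == 0).all().all()


def test_subscale_scores_within_ranges_and_total_consistent(default_cohort):
    for s in SUBSCALES:
        lo, hi = GeneratorConfig().subscale_ranges[s]
        assert default_cohort[s].between(lo, hi).all()
        assert np.issubdtype(default_cohort[s].dtype, np.integer)
    assert (default_cohort["total"] == default_cohort[list(SUBSCALES)].sum(axis=1)).all()
    assert default_cohort["total"].max() <= 148


def test_subscale_means_match_configuration():
    # means at the range centers, so boundary clipping is negligible and the
    # empirical means estimate the configured latent means directly
    means = {"pwb": 14.0, "swb": 14.0, "ewb": 12.0, "fwb": 14.0, "hncs": 20.0}
    cfg = GeneratorConfig(n_subjects=10_000, seed=99, subscale_means=means)
    table = generate_subscales(cfg)
    for s in SUBSCALES:
        se = cfg.subscale_sds[s] / np.sqrt(cfg.n_subjects)
        assert abs(table[s].mean() - means[s]) < 3 * se

    # under the default calibration, clipping at the instrument maxima pulls
    # the highest means inward by at most a quarter point
    default = generate_subscales(GeneratorConfig(n_subjects=10_000, seed=99))
    for s in SUBSCALES:
        assert abs(default[s].mean() - GeneratorConfig().subscale_means[s]) < 0.35


def test_same_seed_byte_identical():
    a, b = make_cohort(GeneratorConfig(n_subjects=300, seed=5)), make_cohort(
        GeneratorConfig(n_subjects=300, seed=5)
    )
    bufs = []
    for t in (a, b):
        buf = io.StringIO()
        t.to_csv(buf, index=False)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]
    c = make_cohort(GeneratorConfig(n_subjects=300, seed=6))
    assert not c.equals(a)


def test_saturated_ceiling_gives_all_ones():
    cfg = GeneratorConfig(
        n_subjects=200, ceiling_coefficients={"intercept": 60.0}
    )
    table = generate_subscales(cfg)
    u = generate_utilities(table, cfg)
    assert (u == 1.0).all()


def test_ceiling_fraction_binomial_interval():
    """Constant ceiling propensity at 9.62% reproduces that rate at n=50,000."""
    p = 0.0962
    cfg = GeneratorConfig(
        n_subjects=50_000, seed=17, ceiling_coefficients={"intercept": float(logit(p))}
    )
    u = generate_utilities(generate_subscales(cfg), cfg)
    frac = np.mean(u == 1.0)
    assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / cfg.n_subjects)


def test_constant_mean_rescaling():
    """C=1, mu = 0.5 everywhere: non-ceiling mean is u_min + (1-u_min)/2."""
    cfg = GeneratorConfig(
        n_subjects=30_000,
        seed=21,
        ceiling_coefficients={"intercept": -30.0},
        component_count=1,
        mixture_weights=(1.0,),
        mean_coefficients=[{"intercept": 0.0}],
        precisions=(30.0,),
    )
    u = generate_utilities(generate_subscales(cfg), cfg)
    expected = -0.391 + 1.391 * 0.5
    assert abs(u.mean() - expected) < 3 * u.std() / np.sqrt(len(u))


def test_utilities_bounded_with_exact_atom(default_cohort):
    u = default_cohort["utility"]
    assert u.between(-0.391, 1.0).all()
    assert (u == 1.0).sum() > 0  # atom is exact, no floating fuzz


def test_make_cohort_schema_and_demographics():
    cfg = GeneratorConfig(n_subjects=1050, seed=1)
    cohort = make_cohort(cfg)
    assert len(cohort) == 1050
    assert list(cohort.columns) == [
        "id", "pwb", "swb", "ewb", "fwb", "hncs", "total", "age", "gender", "utility",
    ]
    assert cohort["age"].between(*cfg.age_range).all()
    assert set(cohort["gender"].unique()) <= {0, 1}


def test_female_fraction_binomial_interval():
    cfg = GeneratorConfig(n_subjects=100_000, seed=2, female_fraction=0.76)
    cohort = make_cohort(cfg)
    se = np.sqrt(0.76 * 0.24 / cfg.n_subjects)
    assert abs(cohort["gender"].mean() - 0.76) < 3 * se


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_subjects": 0},
        {"subscale_ranges": {"pwb": (5, 2)}},
        {"mixture_weights": (0.5, 0.4)},
        {"precisions": (-1.0, 5.0)},
        {"u_min": 1.5},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ValueError):
        GeneratorConfig(**kwargs)


def test_missing_covariate_is_schema_error():
    cfg = GeneratorConfig(n_subjects=10, ceiling_coefficients={"intercept": 0.0, "nope": 1.0})
    table = generate_subscales(cfg)
    with pytest.raises(KeyError):
        generate_utilities(table, cfg)


def test_config_yaml_roundtrip(tmp_path):
    import yaml

    cfg = GeneratorConfig(n_subjects=77, seed=3)
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    assert GeneratorConfig.from_yaml(path) == cfg
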