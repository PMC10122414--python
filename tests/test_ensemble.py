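"""Ensemble sampling and two-stage observational filtering."""

import numpy as np
import pytest

from erwbox import standard_pathway
from erwbox.ensemble import (FilterCriteria, ParameterPrior, build_ensemble,
                             filter_dynamic, filter_static, offline_forcing,
                             sample_priors)
from erwbox.slab import SlabParams


@pytest.fixture(scope="module")
def historical():
    return offline_forcing(standard_pathway("mid", end_year=2020), end_year=2020)


@pytest.fixture(scope="module")
def scenario_forcings():
    return [offline_forcing(standard_pathway(s, end_year=2100), end_year=2100)
            for s in ("low", "high")]


def test_sampling_deterministic_and_in_range():
    prior = ParameterPrior()
    a = sample_priors(prior, 500, seed=9)
    b = sample_priors(prior, 500, seed=9)
    for name in ("n0", "b", "lambda_veg", "lambda_0", "gamma", "q10"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        lo, hi, _ = prior.ranges[name]
        v = getattr(a, name)
        assert v.min() >= lo and v.max() <= hi
    assert np.all(a.n0 * a.lambda_veg < 1.0)


def test_degenerate_range_yields_point():
    prior = ParameterPrior()
    prior.ranges["q10"] = (2.0, 2.0, "uniform")
    p = sample_priors(prior, 3, seed=0)
    np.testing.assert_array_equal(p.q10, 2.0)


def test_uniform_sampling_statistics():
    prior = ParameterPrior()
    p = sample_priors(prior, 10000, seed=123)
    lo, hi, _ = prior.ranges["b"]
    se = (hi - lo) / np.sqrt(12 * 10000)
    assert abs(p.b.mean() - 0.5 * (lo + hi)) < 3 * se


def test_static_filter_passes_window_centered_parameters(historical):
    """Parameters engineered so modern soil, NPP and turnover sit near the
    window centers must pass; a 10x-too-slow soil turnover must fail on
    the soil criterion."""
    good = SlabParams(n0=52.0, b=0.5, lambda_veg=0.001, lambda_0=12.0,
                      gamma=0.035, q10=2.0)
    bad_gamma = SlabParams(n0=np.array([52.0]), b=np.array([0.5]),
                           lambda_veg=np.array([0.001]), lambda_0=np.array([12.0]),
                           gamma=np.array([0.0035]), q10=np.array([2.0]))
    params = SlabParams(
        n0=np.array([52.0, 52.0]), b=np.array([0.5, 0.5]),
        lambda_veg=np.array([0.001, 0.001]), lambda_0=np.array([12.0, 12.0]),
        gamma=np.array([0.035, 0.0035]), q10=np.array([2.0, 2.0]))
    mask, diag = filter_static(params, historical, FilterCriteria())
    assert bool(mask[0])
    assert not bool(mask[1])
    assert not bool(diag["pass_soil"][1])  # soil stock ~10x window


def test_dynamic_filter_envelope_limits(historical, scenario_forcings):
    params = sample_priors(ParameterPrior(), 300, seed=4)
    static_mask, _ = filter_static(params, historical, FilterCriteria())
    sub = params.subset(static_mask)
    if len(sub) == 0:
        pytest.skip("no static survivors in this tiny draw")
    wide = FilterCriteria(delta_v_window_gtc=(-1e9, 1e9),
                          delta_s_window_gtc=(-1e9, 1e9))
    assert filter_dynamic(sub, scenario_forcings, wide).all()
    narrow = FilterCriteria(delta_v_window_gtc=(0.0, 1e-9),
                            delta_s_window_gtc=(0.0, 1e-9))
    assert not filter_dynamic(sub, scenario_forcings, narrow).any()


def test_tightening_envelope_shrinks_accepted_set(historical, scenario_forcings):
    params = sample_priors(ParameterPrior(), 800, seed=6)
    static_mask, _ = filter_static(params, historical, FilterCriteria())
    sub = params.subset(static_mask)
    loose = filter_dynamic(sub, scenario_forcings,
                           FilterCriteria(delta_v_window_gtc=(-100.0, 500.0),
                                          delta_s_window_gtc=(-400.0, 300.0)))
    tight = filter_dynamic(sub, scenario_forcings,
                           FilterCriteria(delta_v_window_gtc=(-25.0, 300.0),
                                          delta_s_window_gtc=(-200.0, 100.0)))
    assert np.all(loose[tight])  # tight-accepted is a subset of loose-accepted
    assert tight.sum() <= loose.sum()


def test_filtering_is_pure(historical):
    params = sample_priors(ParameterPrior(), 200, seed=8)
    m1, _ = filter_static(params, historical, FilterCriteria())
    m2, _ = filter_static(params, historical, FilterCriteria())
    np.testing.assert_array_equal(m1, m2)


def test_build_ensemble_reproducible_and_logged(historical, scenario_forcings):
    ens1 = build_ensemble(ParameterPrior(), FilterCriteria(), 3000, 50, 13,
                          historical, scenario_forcings)
    ens2 = build_ensemble(ParameterPrior(), FilterCriteria(), 3000, 50, 13,
                          historical, scenario_forcings)
    np.testing.assert_array_equal(ens1.params.n0, ens2.params.n0)
    assert ens1.counts == ens2.counts
    assert set(ens1.manifest.columns) >= {"member", "pass_static", "pass_dynamic", "seed"}
    assert ens1.counts["n_pass_static"] >= ens1.counts["n_pass_dynamic"]


def test_all_pass_criteria_keep_every_member(historical):
    """With windows spanning every draw, the ensemble is the full sample."""
    wide = FilterCriteria(soil_window_gtc=(0.0, 1e9), npp_window_gtc_yr=(0.0, 1e9),
                          turnover_window_yr=(0.0, 1e9),
                          delta_v_window_gtc=(-1e9, 1e9),
                          delta_s_window_gtc=(-1e9, 1e9))
    sc = [historical]
    ens = build_ensemble(ParameterPrior(), wide, 40, 40, 21, historical, sc)
    assert len(ens) == 40


def test_prior_validation():
    with pytest.raises(ValueError):
        ParameterPrior(ranges={"n0": (50.0, 40.0, "uniform")})
    with pytest.raises(ValueError):
        ParameterPrior(ranges={"gamma": (-0.1, 0.1, "log")})
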