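"""Logistic selection curves, paired-gear likelihood, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krillselect.selectivity import (
    CatchData,
    DegenerateSelectionError,
    SelectionCurve,
    bootstrap_ci,
    fit_covered_codend,
    fit_paired_gear,
    logistic_retention,
    retention_length,
    _paired_nll,
)
from krillselect.synthetic import SyntheticConfig, gen_paired_catch, with_seed

EXP = SelectionCurve(32.72, 4.85)


def test_retention_at_quantile_lengths():
    assert logistic_retention(EXP.l50, EXP) == pytest.approx(0.5)
    assert logistic_retention(EXP.l50 + EXP.sr / 2, EXP) == pytest.approx(0.75)
    assert logistic_retention(27.87, EXP) == pytest.approx(0.10, abs=5e-4)


def test_retention_lengths_match_published_table():
    # L50 +- SR give the 10% and 90% retention lengths exactly
    assert retention_length(50, EXP) == pytest.approx(32.72)
    assert retention_length(10, EXP) == pytest.approx(32.72 - 4.85, abs=1e-12)
    assert retention_length(90, EXP) == pytest.approx(32.72 + 4.85, abs=1e-12)
    assert retention_length(25, EXP) == pytest.approx(30.295, abs=1e-3)
    for bad in (0.0, 100.0, -3.0):
        with pytest.raises(ValueError):
            retention_length(bad, EXP)


@settings(deadline=None, max_examples=50)
@given(
    l50=st.floats(10.0, 60.0),
    sr=st.floats(0.5, 12.0),
    i=st.floats(0.5, 99.5),
)
def test_retention_length_is_exact_inverse(l50, sr, i):
    curve = SelectionCurve(l50, sr)
    li = retention_length(i, curve)
    assert abs(logistic_retention(li, curve) - i / 100.0) < 1e-12
    assert retention_length(75, curve) - retention_length(25, curve) == pytest.approx(sr)
    assert retention_length(90, curve) - retention_length(10, curve) == pytest.approx(2 * sr)


def test_covered_codend_recovers_simulated_curve():
    rng = np.random.default_rng(8)
    truth = SelectionCurve(33.0, 5.0)
    lengths = rng.uniform(20.0, 46.0, 5000)
    retained = rng.random(5000) < truth.retention(lengths)
    fit = fit_covered_codend(lengths, retained)
    assert not fit.knife_edge
    assert fit.curve.l50 == pytest.approx(33.0, abs=0.3)
    assert fit.curve.sr == pytest.approx(5.0, abs=0.5)


def test_covered_codend_degenerate_and_knife_edge():
    with pytest.raises(DegenerateSelectionError):
        fit_covered_codend([20, 30, 40], [1, 1, 1])
    lengths = np.arange(20.0, 46.0)
    fit = fit_covered_codend(lengths, (lengths > 33).astype(int))
    assert fit.knife_edge
    assert fit.curve.l50 == pytest.approx(33.5, abs=0.51)
    assert fit.curve.sr == pytest.approx(1e-3)


def test_paired_gear_sp_limit_when_fully_retained():
    # lengths far above L50: p_l -> SP, so SP_hat -> test share
    rng = np.random.default_rng(12)
    lengths = np.arange(45.0, 60.0)
    n = rng.integers(30, 60, len(lengths))
    nt = rng.binomial(n, 0.55)
    data = CatchData.from_counts(lengths, nt, n - nt)
    res = fit_paired_gear(data)
    share = nt.sum() / n.sum()
    assert res.sp == pytest.approx(share, abs=0.02)


def test_paired_gear_recovers_generating_parameters():
    cfg = SyntheticConfig(seed=21)
    data = gen_paired_catch(cfg)
    res = fit_paired_gear(data)
    boot = bootstrap_ci(data, reps=100, seed=3)
    for key, truth in [("l50", 32.72), ("sr", 4.85), ("sp", 0.55)]:
        lo, hi = boot.ci[key]
        assert lo <= truth <= hi
    assert res.dof == (data.pooled()[["nt", "nc"]].sum(axis=1) > 0).sum() - 3
    assert 0.0 <= res.p_value <= 1.0


def test_perfect_fit_data_has_near_zero_deviance():
    lengths = np.arange(22.0, 50.0)
    n = np.full(len(lengths), 1000)
    p = 0.55 * EXP.retention(lengths) / (0.55 * EXP.retention(lengths) + 0.45)
    nt = np.round(n * p).astype(int)
    res = fit_paired_gear(CatchData.from_counts(lengths, nt, n - nt))
    assert res.deviance < 1.0
    assert res.p_value > 0.999
    assert res.l50 == pytest.approx(32.72, abs=0.05)
    assert res.sr == pytest.approx(4.85, abs=0.1)
    assert res.sp == pytest.approx(0.55, abs=0.005)


def test_optimised_likelihood_beats_truth():
    for seed in (1, 2, 3):
        data = gen_paired_catch(SyntheticConfig(seed=seed))
        res = fit_paired_gear(data)
        pooled = data.pooled()
        args = (
            pooled["length"].to_numpy(float),
            pooled["nt"].to_numpy(float),
            pooled["nc"].to_numpy(float),
        )
        nll_truth = _paired_nll(
            np.array([32.72, np.log(4.85), np.log(0.55 / 0.45)]), *args
        )
        assert -res.loglik <= nll_truth + 1e-6


def test_l50_error_shrinks_with_sample_size():
    errs = {}
    for factor in (1, 10):
        cfg = SyntheticConfig(seed=0, test_total=393 * factor, control_total=416 * factor)
        e = []
        for s in range(12):
            res = fit_paired_gear(gen_paired_catch(with_seed(cfg, 1000 + s)))
            e.append(abs(res.l50 - 32.72))
        errs[factor] = np.mean(e)
    assert errs[10] < errs[1]


def test_bootstrap_contains_point_estimate_and_is_reproducible():
    data = gen_paired_catch(SyntheticConfig(seed=5))
    a = bootstrap_ci(data, reps=100, seed=9)
    b = bootstrap_ci(data, reps=100, seed=9)
    for key, val in [("l50", a.estimate.l50), ("sr", a.estimate.sr), ("sp", a.estimate.sp)]:
        lo, hi = a.ci[key]
        assert lo <= val <= hi
        assert a.ci[key] == b.ci[key]
    assert set(a.li_ci) == set(range(5, 100, 5))
    assert (a.curve_band["ci_low"] <= a.curve_band["ci_high"]).all()
    with pytest.raises(ValueError):
        bootstrap_ci(data, reps=50)


def test_single_haul_bootstrap_warns():
    data = gen_paired_catch(SyntheticConfig(seed=6, n_hauls=1))
    with pytest.warns(UserWarning):
        bootstrap_ci(data, reps=100, seed=1)


def test_catch_data_validation():
    with pytest.raises(ValueError):
        CatchData.from_counts([30.0, 31.0], [1, -2], [3, 4])
    with pytest.raises(ValueError):
        CatchData.from_counts([30.0, 31.0], [0, 1], [0, 1])  # < 3 classes
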