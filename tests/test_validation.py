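"""External-validation metric battery against an independent direct-formula oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxiqspr import (
    MetricReport,
    classify_quality,
    metric_battery,
    systematic_error_check,
    trim_high_residuals,
)


def oracle_metrics(obs, pred, train_mean):
    """Brute-force reimplementation with plain Python loops."""
    n = len(obs)
    my = sum(obs) / n
    mp = sum(pred) / n
    sxy = sum((a - my) * (b - mp) for a, b in zip(obs, pred))
    sxx = sum((a - my) ** 2 for a in obs)
    spp = sum((b - mp) ** 2 for b in pred)
    r2 = (sxy / math.sqrt(sxx * spp)) ** 2 if spp > 0 else 0.0

    k = sum(a * b for a, b in zip(obs, pred)) / sum(b * b for b in pred)
    r2_0 = 1 - sum((a - k * b) ** 2 for a, b in zip(obs, pred)) / sxx
    kp = sum(a * b for a, b in zip(obs, pred)) / sum(a * a for a in obs)
    r2p_0 = 1 - sum((b - kp * a) ** 2 for a, b in zip(obs, pred)) / spp

    rm2 = r2 * (1 - math.sqrt(abs(r2 - r2_0)))
    rm2p = r2 * (1 - math.sqrt(abs(r2 - r2p_0)))
    ccc = 2 * (sxy / n) / (sxx / n + spp / n + (my - mp) ** 2)
    press = sum((a - b) ** 2 for a, b in zip(obs, pred))
    q2_f1 = 1 - press / sum((a - train_mean) ** 2 for a in obs)
    q2_f2 = 1 - press / sxx
    res = [a - b for a, b in zip(obs, pred)]
    rmse = math.sqrt(sum(r * r for r in res) / n)
    mae = sum(abs(r) for r in res) / n
    abs_res = [abs(r) for r in res]
    m = sum(abs_res) / n
    sd = math.sqrt(sum((r - m) ** 2 for r in abs_res) / (n - 1))
    return {
        "R2": r2, "R2_0": r2_0, "R2p_0": r2p_0,
        "rm2": rm2, "rm2_prime": rm2p,
        "rm2_avg": (rm2 + rm2p) / 2, "rm2_delta": abs(rm2 - rm2p),
        "CCC": ccc, "Q2_F1": q2_f1, "Q2_F2": q2_f2,
        "RMSE": rmse, "MAE": mae, "SD": sd, "MAE_plus_3SD": mae + 3 * sd,
    }


def test_battery_matches_oracle_on_random_vectors(rng):
    for _ in range(100):
        n = int(rng.integers(5, 40))
        obs = rng.normal(3, 2, n)
        pred = obs + rng.normal(0, 1, n)
        train_mean = float(rng.normal(3, 1))
        report = metric_battery(obs, pred, train_mean=train_mean)
        expected = oracle_metrics(obs.tolist(), pred.tolist(), train_mean)
        for key, val in expected.items():
            assert getattr(report, key) == pytest.approx(val, abs=1e-10), key


def test_perfect_prediction():
    r = metric_battery([1, 2, 3, 4], [1, 2, 3, 4], train_mean=2.0)
    assert r.R2 == pytest.approx(1)
    assert r.R2_0 == pytest.approx(1)
    assert r.CCC == pytest.approx(1)
    assert r.Q2_F2 == pytest.approx(1)
    assert r.MAE == 0 and r.RMSE == 0


def test_ccc_hand_example_constant_shift():
    # var = 1.25 each, shift 1: CCC = 2*1.25 / (1.25 + 1.25 + 1)
    r = metric_battery([1, 2, 3, 4], [2, 3, 4, 5])
    assert r.R2 == pytest.approx(1)
    assert r.CCC == pytest.approx(2 * 1.25 / 3.5, abs=1e-4)
    assert r.CCC == pytest.approx(0.7143, abs=1e-4)


def test_prediction_at_test_mean_gives_zero_q2f2():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    pred = np.full(4, obs.mean())
    r = metric_battery(obs, pred)
    assert r.Q2_F2 == pytest.approx(0)


def test_zero_variance_obs_rejected():
    with pytest.raises(ValueError, match="variance"):
        metric_battery([2, 2, 2, 2], [1, 2, 3, 4])


@settings(derandomize=True, max_examples=50)
@given(
    shift=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 10_000),
)
def test_shift_invariance_and_ccc_symmetry(shift, seed):
    """Adding a constant to both vectors leaves R2, CCC, MAE unchanged;
    CCC is symmetric under exchanging observed and predicted."""
    r = np.random.default_rng(seed)
    obs = r.normal(0, 1, 12)
    pred = obs + r.normal(0, 0.5, 12)
    a = metric_battery(obs, pred)
    b = metric_battery(obs + shift, pred + shift)
    assert a.R2 == pytest.approx(b.R2, abs=1e-9)
    assert a.CCC == pytest.approx(b.CCC, abs=1e-9)
    assert a.MAE == pytest.approx(b.MAE, abs=1e-9)
    swapped = metric_battery(pred, obs)
    assert a.CCC == pytest.approx(swapped.CCC, abs=1e-9)


@pytest.mark.parametrize("n,fraction,expected", [(20, 0.05, 1), (123, 0.05, 7), (10, 0.0, 0)])
def test_trim_count_ceiling_rule(rng, n, fraction, expected):
    obs = rng.normal(0, 1, n)
    pred = obs + rng.normal(0, 1, n)
    o, p, removed = trim_high_residuals(obs, pred, fraction)
    assert len(removed) == expected
    assert len(o) == n - expected


def test_trim_never_increases_errors(rng):
    for _ in range(20):
        obs = rng.normal(0, 2, 30)
        pred = obs + rng.normal(0, 1, 30)
        before = metric_battery(obs, pred)
        o, p, _ = trim_high_residuals(obs, pred, 0.1)
        after = metric_battery(o, p)
        assert after.MAE <= before.MAE + 1e-12
        assert after.RMSE <= before.RMSE + 1e-12


def _report(**kw):
    base = dict(
        n_used=20, R2=0.99, R2_0=0.99, R2p_0=0.98, rm2=0.95, rm2_prime=0.94,
        rm2_avg=0.945, rm2_delta=0.01, CCC=0.99, Q2_F1=0.95, Q2_F2=0.95,
        RMSE=0.1, MAE=0.08, SD=0.05, MAE_plus_3SD=0.23,
    )
    base.update(kw)
    return MetricReport(**base)


def test_quality_high_when_all_rules_met():
    rng_range = 7.057
    rep = _report(MAE=0.06 * rng_range, SD=0.01 * rng_range,
                  MAE_plus_3SD=0.09 * rng_range)
    assert classify_quality(rep, rng_range) == "high"


def test_quality_low_on_large_mae():
    rep = _report(MAE=0.25 * 7.057, MAE_plus_3SD=0.9)
    assert classify_quality(rep, 7.057) == "low"


def test_quality_moderate_for_typical_external_set():
    # plausible external-test battery: strong fit but biased through-origin
    rep = _report(
        R2=0.8204, R2_0=0.8115, R2p_0=0.5555, CCC=0.8763,
        rm2_avg=0.6798, rm2_delta=0.1673,
        MAE=0.3146, SD=0.2740, MAE_plus_3SD=1.1367,
    )
    assert classify_quality(rep, 7.057) == "moderate"


def test_quality_threshold_is_ten_percent_of_range():
    rng_range = 7.057
    good = _report(MAE=0.70, MAE_plus_3SD=0.70, SD=0.0)
    bad = _report(MAE=0.71, MAE_plus_3SD=0.71, SD=0.0)
    assert classify_quality(good, rng_range) == "high"
    assert classify_quality(bad, rng_range) != "high"


def test_systematic_error_rules(rng):
    obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    sym = obs + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
    assert systematic_error_check(obs, sym) is False
    assert systematic_error_check(obs, obs + 1.0) is True
    gauss = obs = rng.normal(0, 1, 100)
    assert systematic_error_check(gauss + rng.normal(0, 0.3, 100), gauss) is False
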