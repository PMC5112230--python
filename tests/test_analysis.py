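"""Psychometric fits, window bookkeeping, drift regression, group stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from svvdrift import (
    compute_aftereffect,
    fit_drift,
    fit_psychometric,
    pool_group,
    sliding_series,
    window_spans,
)
from svvdrift.errors import InsufficientDataError


def _logistic_responses(rng, devs, pse, scale):
    return rng.random(devs.size) < expit((devs - pse) / scale)


def test_fit_recovers_generator_pse_and_precision():
    """The generating logistic is the oracle: at n = 5000 the fitted PSE and
    precision land on the planted values."""
    rng = np.random.default_rng(12)
    devs = rng.uniform(-7.9, 0.1, 5000)
    resp = _logistic_responses(rng, devs, pse=-3.9, scale=0.7 / np.log(3))
    fit = fit_psychometric(devs, resp)
    assert fit.converged
    assert fit.pse == pytest.approx(-3.9, abs=0.05)
    assert fit.precision == pytest.approx(0.70, abs=0.03)


def test_fit_mirror_symmetry():
    rng = np.random.default_rng(13)
    devs = rng.uniform(-6, 6, 800)
    resp = _logistic_responses(rng, devs, pse=1.5, scale=1.0)
    fit = fit_psychometric(devs, resp)
    mirrored = fit_psychometric(-devs, ~resp)
    assert mirrored.pse == pytest.approx(-fit.pse, abs=1e-6)
    assert mirrored.precision == pytest.approx(fit.precision, abs=1e-6)


def test_fit_separable_step_reports_fallback_near_threshold():
    devs = np.linspace(-3, 7, 60)
    resp = devs > 2.0  # deterministic step
    fit = fit_psychometric(devs, resp)
    assert not fit.converged
    assert fit.pse == pytest.approx(2.0, abs=0.3)
    assert fit.precision > 0  # ridge fallback still yields a finite slope


def test_fit_unanimous_uses_edge_rule():
    devs = np.linspace(5, 25, 40)
    fit = fit_psychometric(devs, np.ones(40, bool))
    assert not fit.converged
    assert fit.pse == 5.0
    assert np.isnan(fit.precision)


def test_fit_preconditions():
    with pytest.raises(InsufficientDataError):
        fit_psychometric(np.arange(10.0), np.zeros(10, bool))
    with pytest.raises(InsufficientDataError):
        fit_psychometric(np.full(40, 2.0), np.r_[np.ones(20, bool), np.zeros(20, bool)])


@pytest.mark.parametrize(
    "n, expected",
    [
        (500, [(51, 150), (101, 200), (151, 250), (201, 300), (251, 350),
               (301, 400), (351, 450), (401, 500)]),
        (150, [(51, 150)]),
        (100, []),
        (149, []),
    ],
)
def test_window_spans_enumeration(n, expected):
    assert window_spans(n) == expected


@given(n=st.integers(0, 1200))
@settings(max_examples=200, derandomize=True)
def test_window_spans_match_brute_force(n):
    """Every candidate 100-trial window whose start falls on the post-discard
    50-trial grid, and no other, is emitted."""
    grid = {51 + 50 * k for k in range(100)}
    brute = [
        (s, s + 99) for s in sorted(grid) if s + 99 <= n
    ]
    assert window_spans(n) == brute


def _synthetic_log(rng, seg_plan, pse_by_seg, scale=0.6):
    """Trial log straight from the response model, no task loop."""
    rows = []
    t = 0.0
    idx = 0
    for seg_id, (angle, n) in enumerate(seg_plan):
        for _ in range(n):
            idx += 1
            dev = rng.uniform(pse_by_seg[seg_id] - 5, pse_by_seg[seg_id] + 5)
            resp = "right" if rng.random() < expit((dev - pse_by_seg[seg_id]) / scale) else "left"
            rows.append(
                {
                    "session_id": "syn",
                    "subject_id": "syn",
                    "trial_index": idx,
                    "segment_id": seg_id,
                    "block_index": 0,
                    "head_angle_deg": angle,
                    "hemifield": "top",
                    "deviation_deg": dev,
                    "ray_angle_deg": dev,
                    "response": resp,
                    "reaction_time_ms": 700.0,
                    "onset_time_s": t,
                }
            )
            t += 1.7
    return pd.DataFrame(rows)


def test_sliding_series_counts_and_segment_isolation():
    rng = np.random.default_rng(21)
    log = _synthetic_log(rng, [(0.0, 100), (-20.0, 500), (0.0, 150)], [0.0, -2.0, -4.0])
    series = sliding_series(log)
    counts = series.groupby("segment_kind").size().to_dict()
    assert counts == {"tilt": 8, "posttilt": 1}
    assert (series[series.segment_kind == "tilt"]["first"].to_numpy()
            == np.arange(51, 402, 50)).all()
    # no window crosses a segment boundary: spans stay within segment length
    assert (series["last"] <= 500).all()


def test_fit_drift_on_exact_line():
    trial_mid = np.array([100.5, 150.5, 200.5, 250.5, 300.5])
    series = pd.DataFrame(
        {
            "trial_mid": trial_mid,
            "time_mid_s": trial_mid * 1.8,
            "svv_deg": -0.0108 * trial_mid,
        }
    )
    d = fit_drift(series)
    assert d.slope_per_500_trials == pytest.approx(-5.4, abs=1e-9)
    assert d.slope_per_min == pytest.approx(-0.0108 / 1.8 * 60.0, abs=1e-9)
    assert d.r2 == pytest.approx(1.0)


def test_fit_drift_constant_series_and_minimum_points():
    series = pd.DataFrame(
        {"trial_mid": [100.0, 150.0, 200.0], "time_mid_s": [1, 2, 3], "svv_deg": [2.0] * 3}
    )
    assert fit_drift(series).slope_per_500_trials == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(InsufficientDataError):
        fit_drift(series.iloc[:2])


def test_aftereffect_arithmetic_and_symmetry():
    assert compute_aftereffect([-4.6], -0.7) == pytest.approx(-3.9)
    assert compute_aftereffect([4.6], 0.7) == pytest.approx(3.9)
    assert compute_aftereffect([1.0, 3.0], 2.0) == pytest.approx(0.0)
    with pytest.raises(InsufficientDataError):
        compute_aftereffect([], 0.0)
    with pytest.raises(InsufficientDataError):
        compute_aftereffect([1.0], float("nan"))


def _subject(sid, drift_l, after_l, drift_r, after_r, tdrift=0.0, tafter=0.0):
    return {
        "subject_id": sid,
        "left": {
            "drift_svv": drift_l,
            "aftereffect_svv": after_l,
            "drift_torsion": tdrift,
            "aftereffect_torsion": tafter,
            "baseline_svv": -0.5,
        },
        "right": {
            "drift_svv": drift_r,
            "aftereffect_svv": after_r,
            "drift_torsion": -tdrift,
            "aftereffect_torsion": -tafter,
            "baseline_svv": 0.5,
        },
    }


def test_pool_group_identical_subjects_degenerate():
    subs = [_subject(f"S{i}", -5.0, -4.0, 2.0, 2.5) for i in range(4)]
    gs = pool_group(subs)
    assert gs.condition_means["drift_svv"]["left"]["mean"] == pytest.approx(-5.0)
    assert gs.condition_means["drift_svv"]["left"]["sem"] == pytest.approx(0.0)
    assert gs.tests["drift_svv_vs_zero"]["degenerate"]


def test_pool_group_monotone_coupling_yields_unit_rho():
    rng = np.random.default_rng(31)
    subs = []
    for i in range(12):
        d = rng.normal(-5.0, 2.0)
        subs.append(_subject(f"S{i}", d, 0.7 * d, -d, -0.7 * d))
    gs = pool_group(subs)
    corr = gs.correlations["svv_drift_vs_aftereffect"]
    assert corr["rho"] == pytest.approx(1.0)
    assert corr["significant"]


def test_pool_group_independent_draws_not_significant():
    rng = np.random.default_rng(0)
    subs = [
        _subject(
            f"S{i}",
            rng.normal(-5.4, 4.85),
            rng.normal(-3.9, 2.08),
            rng.normal(2.2, 7.27),
            rng.normal(2.55, 3.46),
            tdrift=rng.normal(-0.8, 1.0),
            tafter=rng.normal(-0.2, 1.0),
        )
        for i in range(12)
    ]
    gs = pool_group(subs)
    assert not gs.correlations["svv_drift_vs_aftereffect"]["significant"]
    assert not gs.correlations["svv_vs_torsion_drift"]["significant"]


def test_pool_group_needs_three_complete_subjects():
    with pytest.raises(InsufficientDataError):
        pool_group([_subject("a", 1, 1, 1, 1), _subject("b", 2, 2, 2, 2)])
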