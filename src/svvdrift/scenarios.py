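"""Deterministic time courses of the model's drift scenarios.

Reproduces the three qualitative mechanisms that can move the SVV during a
sustained tilt — adaptation of the head-in-space sensory signal, drift of
the head-position prior toward the tilt, and growth of the tilt-dependent
sensory noise — each run over a baseline / 15-min tilt / post-tilt
protocol so their signatures can be compared:

* ``sensory_drift``: SVV drifts toward the tilt and keeps a same-signed
  post-tilt aftereffect (the sensory after-response).
* ``prior_drift``: SVV drifts away from the tilt.
* ``noise_growth``: SVV drifts toward the tilt but returns exactly to its
  baseline value upright, since the noise term carries no weight at zero
  tilt — no aftereffect.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .observer import ObserverParams, ScenarioSchedule, apply_scenario, initial_state

__all__ = ["default_schedule", "scenario_time_course", "scenario_summary"]


def default_schedule(kind: str, tilt_angle: float = 20.0) -> ScenarioSchedule:
    """Reference schedule for one named scenario.

    Rates are modest, physiologically plausible choices: a fraction of a
    degree per minute of sensory adaptation, half a degree per minute of
    prior drift, one percentage point per minute of extra noise growth.
    """
    sign = math.copysign(1.0, tilt_angle)
    if kind == "sensory_drift":
        return ScenarioSchedule(
            kind="sensory_drift", tilt_rate=-0.3 * sign, aftereffect_gain=0.8
        )
    if kind == "prior_drift":
        return ScenarioSchedule(
            kind="prior_drift", tilt_rate=0.5, aftereffect_gain=0.8
        )
    if kind == "noise_growth":
        return ScenarioSchedule(kind="noise_growth", tilt_rate=0.01, aftereffect_gain=0.0)
    if kind == "none":
        return ScenarioSchedule()
    raise ConfigurationError(f"unknown scenario kind {kind!r}")


def scenario_time_course(
    kind_or_schedule,
    tilt_angle: float = 20.0,
    baseline_min: float = 2.0,
    tilt_min: float = 15.0,
    posttilt_min: float = 5.0,
    params: ObserverParams | None = None,
    dt_s: float = 1.0,
) -> pd.DataFrame:
    """Deterministic mu_svv trajectory across baseline, tilt and post-tilt.

    ``kind_or_schedule`` is a scenario name (uses :func:`default_schedule`)
    or an explicit :class:`ScenarioSchedule`.
    """
    if params is None:
        params = ObserverParams()
    if isinstance(kind_or_schedule, ScenarioSchedule):
        schedule = kind_or_schedule
    else:
        schedule = default_schedule(kind_or_schedule, tilt_angle)

    spans = (
        ("baseline", 0.0, baseline_min),
        ("tilt", tilt_angle, tilt_min),
        ("posttilt", 0.0, posttilt_min),
    )
    state = initial_state(params, 0.0, schedule)
    rows = []
    t = 0.0
    for segment, head, minutes in spans:
        n = max(int(round(minutes * 60.0 / dt_s)), 1)
        for _ in range(n):
            state = apply_scenario(state, schedule, params, t, segment, head)
            rows.append(
                {
                    "time_s": t,
                    "segment": segment,
                    "head_angle_deg": head,
                    "sensed_head_bias": state.sensed_head_bias,
                    "effective_prior_mean": state.effective_prior_mean,
                    "effective_alpha1": state.effective_alpha1,
                    "mu_svv": state.mu_svv,
                }
            )
            t += dt_s
    return pd.DataFrame(rows)


def scenario_summary(trace: pd.DataFrame) -> dict:
    """Signature numbers of a scenario trace.

    ``tilt_slope_per_min``: fitted linear slope of mu_svv during tilt;
    ``posttilt_offset``: mean post-tilt mu_svv minus mean baseline mu_svv.
    """
    tilt = trace[trace["segment"] == "tilt"]
    base = trace[trace["segment"] == "baseline"]
    post = trace[trace["segment"] == "posttilt"]
    fit = stats.linregress(tilt["time_s"].to_numpy(), tilt["mu_svv"].to_numpy())
    return {
        "baseline_mu": float(base["mu_svv"].mean()),
        "tilt_slope_per_min": float(fit.slope * 60.0),
        "posttilt_offset": float(post["mu_svv"].mean() - base["mu_svv"].mean()),
    }
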