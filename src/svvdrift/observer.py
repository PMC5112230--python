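"""Bayesian observer model of verticality perception under static head tilt.

The observer estimates its head-in-space orientation by combining a noisy
sensory signal (otolith + neck proprioception) with a Gaussian prior peaked
near upright.  The systematic error of the subjective visual vertical (SVV)
that this produces is

    mu_svv = w * (H_S - H_Sp) - (1 - w) * b - dE_H * sin(H_S)

where ``H_S`` is the true head-in-space angle, ``H_Sp`` the prior's peak,
``b`` an additive bias on the sensed head signal (the sensed signal is
``H_S + b``), ``dE_H`` the amplitude of uncompensated ocular counterroll, and

    w = sigma_hat^2 / (sigma_prior^2 + sigma_hat^2),
    sigma_hat = alpha0 + alpha1 * |H_S|.

``w * H_S`` is the Aubert (A-effect) term pulling the SVV toward the head
tilt; ``-dE_H * sin(H_S)`` is the Mueller (E-effect) term pushing it away.
With an unbiased sensor (``b = 0``) and an upright prior peak the expression
reduces to the classic two-term form.  The sensory bias enters through the
posterior mean, so a *decaying* sensed tilt signal (``b`` opposing the tilt)
drives the SVV *toward* the tilt — the signature the drift scenarios below
reproduce.

Angles are in degrees; positive means rightward (clockwise from the
subject's viewpoint) for head tilt, SVV error and torsion alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "SEGMENT_KINDS",
    "ObserverParams",
    "ScenarioSchedule",
    "ObserverState",
    "VirtualObserver",
    "sensory_sd",
    "bayes_weight",
    "svv_error",
    "initial_state",
    "apply_scenario",
    "response_probability",
    "simulate_response",
]

#: Segment labels used throughout the session protocol.
SEGMENT_KINDS = ("baseline", "tilt", "posttilt")

_LN3 = math.log(3.0)

#: Response-window limits of the task, ms (line visible 0.3-1.5 s).
RT_MIN_MS = 300.0
RT_MAX_MS = 1500.0


@dataclass(frozen=True)
class ObserverParams:
    """Static parameters of one virtual observer.

    Defaults are representative published fit values for a healthy adult:
    a prior SD of a few degrees, ~2 deg of sensory noise upright growing
    ~7 %/deg with tilt, and an uncompensated-torsion amplitude that nearly
    cancels the A-effect at 20 deg (hence the mild E-effect typical of
    small tilts).

    Parameters
    ----------
    sigma_prior : float
        SD of the head-position prior, deg (> 0).
    prior_mean : float
        Peak of the head-position prior, deg (0 = upright).
    alpha0 : float
        Sensory noise SD at upright, deg (> 0).
    alpha1 : float
        Proportional growth of sensory noise with |head tilt| (>= 0).
    delta_EH : float
        Amplitude of the uncompensated-torsion term, deg; contributes
        ``-delta_EH * sin(head_angle)`` to the SVV error.
    decision_scale : float
        Logistic scale of the 2AFC decision rule, deg (> 0).  The
        psychometric 75 %-50 % distance ("precision") equals
        ``decision_scale * ln 3``.
    lapse_rate : float
        Stimulus-independent error probability, in [0, 0.1].
    """

    sigma_prior: float = 6.5
    prior_mean: float = 0.0
    alpha0: float = 2.2
    alpha1: float = 0.07
    delta_EH: float = 14.0
    decision_scale: float = 0.7 / _LN3
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_prior) and self.sigma_prior > 0):
            raise InvalidInputError("sigma_prior must be finite and > 0")
        if not np.isfinite(self.prior_mean):
            raise InvalidInputError("prior_mean must be finite")
        if not (np.isfinite(self.alpha0) and self.alpha0 > 0):
            raise InvalidInputError("alpha0 must be finite and > 0")
        if not (np.isfinite(self.alpha1) and self.alpha1 >= 0):
            raise InvalidInputError("alpha1 must be finite and >= 0")
        if not np.isfinite(self.delta_EH):
            raise InvalidInputError("delta_EH must be finite")
        if not (np.isfinite(self.decision_scale) and self.decision_scale > 0):
            raise InvalidInputError("decision_scale must be finite and > 0")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise InvalidInputError("lapse_rate must lie in [0, 0.1]")


_SCENARIO_KINDS = ("none", "sensory_drift", "prior_drift", "noise_growth", "composite")
_FORMS = ("linear", "exponential")


@dataclass(frozen=True)
class ScenarioSchedule:
    """Time course of one model quantity across the tilt protocol.

    ``kind`` selects which quantity drifts while the head is tilted:

    * ``sensory_drift`` — the additive bias ``b`` on the sensed head signal
      accumulates at ``tilt_rate`` deg/min (negative of the tilt sign makes
      the sensed tilt decay, the adaptation scenario).  After the head
      returns upright a residual of the accumulated change — the sensory
      after-response, opposite in sign to the tilt stimulus — is expressed,
      scaled by ``aftereffect_gain`` and decaying with ``aftereffect_decay``.
    * ``prior_drift`` — the prior's peak moves toward the tilted head angle.
    * ``noise_growth`` — ``alpha1`` grows during tilt; upright the noise is
      ``alpha0`` regardless, so this leaves no aftereffect.
    * ``none`` — stationary observer; ``composite`` — one sub-schedule per
      quantity.

    The ``bias_*`` anchors pin the sensory-bias channel at segment starts so
    a cohort generator can plant exact SVV values; ``bias_posttilt`` set to a
    number overrides the gain-based residual.
    """

    kind: str = "none"
    form: str = "linear"
    tilt_rate: float = 0.0  # deg/min of the drifting quantity during tilt
    time_constant: float = 5.0  # min; exponential form only
    aftereffect_gain: float = 0.0
    aftereffect_decay: float = math.inf  # min; inf = persistent residual
    bias_baseline: float = 0.0
    bias_tilt_onset: float = 0.0
    bias_posttilt: float | None = None
    sub: tuple["ScenarioSchedule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _SCENARIO_KINDS:
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown scenario form {self.form!r}")
        if not np.isfinite(self.tilt_rate):
            raise ConfigurationError("tilt_rate must be finite")
        if not (0.0 <= self.aftereffect_gain <= 1.0):
            raise ConfigurationError("aftereffect_gain must lie in [0, 1]")
        if not self.aftereffect_decay > 0:
            raise ConfigurationError("aftereffect_decay must be > 0 (may be inf)")
        if self.kind == "composite" and not self.sub:
            raise ConfigurationError("composite schedule needs sub-schedules")
        if self.sub and any(s.kind == "composite" for s in self.sub):
            raise ConfigurationError("composite sub-schedules cannot nest")


@dataclass
class ObserverState:
    """Time-varying state of a virtual observer.

    ``mu_svv`` is always the model SVV error recomputed from the effective
    values carried here; recomputation is idempotent.  The trailing fields
    are scenario bookkeeping (segment anchors and the change accumulated by
    the end of the tilt segment, needed for the posttilt residual).
    """

    t: float
    head_angle: float
    sensed_head_bias: float
    effective_prior_mean: float
    effective_alpha1: float
    mu_svv: float
    segment: str = "baseline"
    segment_t0: float = 0.0
    tilt_minutes: float = 0.0
    accum: dict = field(default_factory=dict)


def sensory_sd(params: ObserverParams, head_angle: float) -> float:
    """SD of the head-in-space sensory signal at a given tilt, deg.

    ``alpha0 + alpha1 * |head_angle|`` — noise grows linearly with the
    magnitude of the tilt and is therefore an even function of it.
    """
    if not np.isfinite(head_angle):
        raise InvalidInputError("head_angle must be finite")
    return params.alpha0 + params.alpha1 * abs(head_angle)


def bayes_weight(
    params: ObserverParams, head_angle: float, alpha1: float | None = None
) -> float:
    """Weight ``w = sigma_hat^2 / (sigma_prior^2 + sigma_hat^2)`` in [0, 1).

    This is the share of the head estimate ceded to the prior; it multiplies
    the head angle in the SVV error (A-effect strength).
    """
    p = params if alpha1 is None else replace(params, alpha1=alpha1)
    s2 = sensory_sd(p, head_angle) ** 2
    return s2 / (params.sigma_prior**2 + s2)


def svv_error(
    params: ObserverParams,
    head_angle: float,
    sensed_head_bias: float = 0.0,
    prior_mean: float | None = None,
    alpha1: float | None = None,
) -> float:
    """Model SVV error (deg) for a given true head angle and sensory bias.

    ``prior_mean`` / ``alpha1`` override the static parameters with the
    scenario's current effective values.  With ``sensed_head_bias = 0`` and
    ``prior_mean = 0`` this is exactly ``w*H - dE_H*sin(H)``.
    """
    if not np.isfinite(head_angle):
        raise InvalidInputError("head_angle must be finite")
    if not np.isfinite(sensed_head_bias):
        raise InvalidInputError("sensed_head_bias must be finite")
    pm = params.prior_mean if prior_mean is None else prior_mean
    w = bayes_weight(params, head_angle, alpha1)
    return (
        w * (head_angle - pm)
        - (1.0 - w) * sensed_head_bias
        - params.delta_EH * math.sin(math.radians(head_angle))
    )


def initial_state(
    params: ObserverParams,
    head_angle: float = 0.0,
    schedule: ScenarioSchedule | None = None,
) -> ObserverState:
    """State at session start (t = 0, baseline segment)."""
    bias = schedule.bias_baseline if schedule is not None and _has_bias(schedule) else 0.0
    return ObserverState(
        t=0.0,
        head_angle=head_angle,
        sensed_head_bias=bias,
        effective_prior_mean=params.prior_mean,
        effective_alpha1=params.alpha1,
        mu_svv=svv_error(params, head_angle, bias),
    )


def _has_bias(schedule: ScenarioSchedule) -> bool:
    if schedule.kind == "sensory_drift":
        return True
    if schedule.kind == "composite":
        return any(s.kind == "sensory_drift" for s in schedule.sub)
    return False


def _drift_amount(schedule: ScenarioSchedule, minutes: float) -> float:
    """Accumulated change of the drifting quantity after ``minutes`` of tilt."""
    if schedule.form == "linear":
        return schedule.tilt_rate * minutes
    tau = schedule.time_constant
    return schedule.tilt_rate * tau * -math.expm1(-minutes / tau)


def _residual(schedule: ScenarioSchedule, accumulated: float, minutes: float) -> float:
    """Posttilt residual of an accumulated change, washing out over time."""
    r = schedule.aftereffect_gain * accumulated
    if math.isfinite(schedule.aftereffect_decay):
        r *= math.exp(-minutes / schedule.aftereffect_decay)
    return r


def _channels(schedule: ScenarioSchedule) -> tuple[ScenarioSchedule, ...]:
    return schedule.sub if schedule.kind == "composite" else (schedule,)


def apply_scenario(
    state: ObserverState,
    schedule: ScenarioSchedule,
    params: ObserverParams,
    t: float,
    segment: str,
    head_angle: float | None = None,
) -> ObserverState:
    """Advance the observer to time ``t`` within ``segment``.

    ``t`` must be non-decreasing across successive calls of one session.
    On a segment change the anchor time resets; leaving the tilt segment
    freezes each channel's accumulated change for the posttilt residual.
    Returns a new state with ``mu_svv`` recomputed.
    """
    if segment not in SEGMENT_KINDS:
        raise ConfigurationError(f"unknown segment {segment!r}")
    if t < state.t:
        raise InvalidInputError("t must be non-decreasing within a session")
    head = state.head_angle if head_angle is None else head_angle

    segment_t0 = state.segment_t0
    tilt_minutes = state.tilt_minutes
    accum = dict(state.accum)
    if segment != state.segment:
        if state.segment == "tilt":
            # freeze each channel's realized change at the end of the tilt
            tilt_minutes = (state.t - state.segment_t0) / 60.0
            for ch in _channels(schedule):
                if ch.kind == "sensory_drift":
                    accum[ch.kind] = state.sensed_head_bias - ch.bias_tilt_onset
                elif ch.kind == "prior_drift":
                    accum[ch.kind] = state.effective_prior_mean - params.prior_mean
                elif ch.kind == "noise_growth":
                    accum[ch.kind] = state.effective_alpha1 - params.alpha1
        segment_t0 = t
    minutes = (t - segment_t0) / 60.0

    bias = 0.0
    prior = params.prior_mean
    alpha1 = params.alpha1
    for ch in _channels(schedule):
        if ch.kind == "none":
            continue
        if ch.kind == "sensory_drift":
            bias = _bias_at(ch, segment, minutes, accum)
        elif ch.kind == "prior_drift":
            prior = _prior_at(ch, params, head, segment, minutes, accum)
        elif ch.kind == "noise_growth":
            alpha1 = _alpha1_at(ch, params, segment, minutes, accum)

    return ObserverState(
        t=t,
        head_angle=head,
        sensed_head_bias=bias,
        effective_prior_mean=prior,
        effective_alpha1=alpha1,
        mu_svv=svv_error(params, head, bias, prior, alpha1),
        segment=segment,
        segment_t0=segment_t0,
        tilt_minutes=tilt_minutes,
        accum=accum,
    )


def _bias_at(ch: ScenarioSchedule, segment: str, minutes: float, accum: dict) -> float:
    if segment == "baseline":
        return ch.bias_baseline
    if segment == "tilt":
        return ch.bias_tilt_onset + _drift_amount(ch, minutes)
    # posttilt: explicit anchor wins; otherwise a gain-scaled residual of the
    # accumulated drift (same sign as the drift, i.e. opposite to the tilt).
    if ch.bias_posttilt is not None:
        target = ch.bias_posttilt
        if math.isfinite(ch.aftereffect_decay):
            return ch.bias_baseline + (target - ch.bias_baseline) * math.exp(
                -minutes / ch.aftereffect_decay
            )
        return target
    return ch.bias_baseline + _residual(ch, accum.get(ch.kind, 0.0), minutes)


def _prior_at(
    ch: ScenarioSchedule,
    params: ObserverParams,
    head: float,
    segment: str,
    minutes: float,
    accum: dict,
) -> float:
    if segment == "baseline":
        return params.prior_mean
    if segment == "tilt":
        shift = math.copysign(abs(_drift_amount(ch, minutes)), head)
        moved = params.prior_mean + shift
        # the prior cannot overshoot the actual head position
        if abs(moved - params.prior_mean) > abs(head - params.prior_mean):
            return head
        return moved
    return params.prior_mean + _residual(ch, accum.get(ch.kind, 0.0), minutes)


def _alpha1_at(
    ch: ScenarioSchedule,
    params: ObserverParams,
    segment: str,
    minutes: float,
    accum: dict,
) -> float:
    if segment == "baseline":
        return params.alpha1
    if segment == "tilt":
        return max(params.alpha1 + _drift_amount(ch, minutes), 0.0)
    return max(params.alpha1 + _residual(ch, accum.get(ch.kind, 0.0), minutes), 0.0)


def response_probability(
    state: ObserverState, params: ObserverParams, deviation: float
) -> float:
    """P(respond "right") for a line at ``deviation`` deg from the meridian.

    Lapse-contaminated logistic: ``lam/2 + (1-lam)*F((d - mu_svv)/scale)``.
    At ``deviation = mu_svv`` and zero lapse this is exactly 0.5 (the PSE).
    """
    if not np.isfinite(deviation) or not (-90.0 < deviation <= 90.0):
        raise InvalidInputError("deviation must lie in (-90, 90]")
    lam = params.lapse_rate
    z = (deviation - state.mu_svv) / params.decision_scale
    return lam / 2.0 + (1.0 - lam) * float(expit(z))


def simulate_response(
    state: ObserverState,
    params: ObserverParams,
    deviation: float,
    rng: np.random.Generator,
    rt_mean_ms: float = 660.0,
    rt_shape: float = 0.15,
) -> tuple[str, float]:
    """One Bernoulli 2AFC response plus a reaction time.

    The reaction time is log-normal with the requested mean and shape
    (SD of log RT), censored to the task's 300-1500 ms response window.
    """
    p_right = response_probability(state, params, deviation)
    response = "right" if rng.random() < p_right else "left"
    mu_log = math.log(rt_mean_ms) - rt_shape**2 / 2.0
    rt = float(np.exp(rng.normal(mu_log, rt_shape)))
    rt = min(max(rt, RT_MIN_MS), RT_MAX_MS)
    return response, rt


@dataclass(frozen=True)
class VirtualObserver:
    """Bundle of everything the task engine needs to run one session.

    Decision noise and mean reaction time are condition-specific (judging a
    tilted world is slower and noisier), so both are keyed by segment kind
    and fall back to the static parameters when unset.
    """

    params: ObserverParams
    schedule: ScenarioSchedule = ScenarioSchedule()
    decision_scale_by_segment: dict | None = None
    rt_mean_ms_by_segment: dict | None = None
    rt_shape: float = 0.15

    def params_for(self, segment: str) -> ObserverParams:
        if self.decision_scale_by_segment is None:
            return self.params
        scale = self.decision_scale_by_segment.get(segment)
        if scale is None:
            return self.params
        return replace(self.params, decision_scale=scale)

    def rt_mean_for(self, segment: str) -> float:
        defaults = {"baseline": 640.0, "tilt": 686.0, "posttilt": 661.0}
        table = self.rt_mean_ms_by_segment or defaults
        return float(table.get(segment, defaults[segment]))
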