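"""Synthetic binocular ocular-torsion traces.

Emulates the output stream of a video torsion tracker: 100 Hz samples per
eye with < 0.1 deg measurement noise.  During a lateral head tilt the eyes
counterroll opposite to the tilt with a gain of roughly 20 %, then drift
slowly *toward* the tilt over the sustained-tilt period, and may keep a
small same-signed offset after the head returns upright.  A static
interocular offset is included so binocular averaging is exercised; the
pre-tilt upright recording serves as the reference baseline.

Sign convention matches the rest of the package: positive = rightward
(clockwise from the subject's viewpoint), so counterroll during a right
tilt is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "TorsionParams",
    "TorsionTrace",
    "SegmentSpan",
    "timeline_from_log",
    "generate_trace",
    "trial_torsion",
    "per_trial_torsion",
    "reference_to_baseline",
]


@dataclass(frozen=True)
class TorsionParams:
    """Generator parameters for one session's torsion trace.

    ``drift_per_500trials`` and ``aftereffect_deg`` are signed (toward the
    tilt is the typical direction, i.e. same sign as the head angle).
    ``noise_sd`` must stay below the tracker's stated 0.1 deg noise level.
    """

    counterroll_gain: float = 0.20
    drift_per_500trials: float = 0.0
    aftereffect_deg: float = 0.0
    noise_sd: float = 0.08
    sample_rate: float = 100.0
    interocular_offset: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.counterroll_gain <= 1.0):
            raise ConfigurationError("counterroll_gain must lie in [0, 1]")
        if not (0.0 <= self.noise_sd < 0.1):
            raise ConfigurationError("noise_sd must lie in [0, 0.1)")
        if not self.sample_rate > 0:
            raise ConfigurationError("sample_rate must be > 0")


@dataclass
class TorsionTrace:
    """Uniformly sampled binocular torsion, deg, positive rightward."""

    time_s: np.ndarray
    left_deg: np.ndarray
    right_deg: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.left_deg) == len(self.right_deg)):
            raise InvalidInputError("trace arrays must have equal length")

    def binocular(self) -> np.ndarray:
        return (self.left_deg + self.right_deg) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "left_deg": self.left_deg, "right_deg": self.right_deg}
        )


@dataclass(frozen=True)
class SegmentSpan:
    """One head-position epoch of the session timeline."""

    t_start: float
    t_end: float
    head_angle: float
    kind: str  # baseline / tilt / posttilt
    n_trials: int


def timeline_from_log(log: pd.DataFrame, pad_s: float = 1.0) -> list[SegmentSpan]:
    """Head-position epochs inferred from a trial log.

    Each segment spans from the end of the previous one (the head moves at
    the start of the inter-segment pause) to its own last response; the
    final segment is padded by ``pad_s``.
    """
    spans: list[SegmentSpan] = []
    prev_end = 0.0
    seg_ids = sorted(log["segment_id"].unique())
    saw_tilt = False
    for seg_id in seg_ids:
        seg = log[log["segment_id"] == seg_id]
        angle = float(seg["head_angle_deg"].iloc[0])
        rt = seg["reaction_time_ms"].fillna(1500.0) / 1000.0
        t_end = float((seg["onset_time_s"] + rt).max())
        if angle != 0.0:
            kind = "tilt"
            saw_tilt = True
        else:
            kind = "posttilt" if saw_tilt else "baseline"
        n_answered = int((seg["response"] != "missed").sum())
        spans.append(SegmentSpan(prev_end, t_end, angle, kind, n_answered))
        prev_end = t_end
    last = spans[-1]
    spans[-1] = SegmentSpan(last.t_start, last.t_end + pad_s, last.head_angle, last.kind, last.n_trials)
    return spans


def generate_trace(
    params: TorsionParams,
    timeline: list[SegmentSpan],
    rng: np.random.Generator,
) -> TorsionTrace:
    """Simulate the binocular torsion trace over a session timeline.

    Per eye: ``-gain * head_angle(t)`` (instantaneous counterroll; the
    30-s pauses hide any transient) plus a linear drift ramp across each
    tilt segment scaled to that segment's trial count, a constant offset in
    post-tilt segments, half the interocular offset (left +, right -) and
    white measurement noise.
    """
    if not timeline:
        raise InvalidInputError("empty timeline")
    total = timeline[-1].t_end
    n = int(np.floor(total * params.sample_rate)) + 1
    time_s = np.arange(n) / params.sample_rate

    base = np.zeros(n)
    for span in timeline:
        mask = (time_s >= span.t_start) & (time_s < span.t_end)
        if span is timeline[-1]:
            mask = (time_s >= span.t_start)
        base[mask] = -params.counterroll_gain * span.head_angle
        if span.kind == "tilt" and span.t_end > span.t_start:
            total_drift = params.drift_per_500trials * (span.n_trials / 500.0)
            frac = (time_s[mask] - span.t_start) / (span.t_end - span.t_start)
            base[mask] += total_drift * frac
        elif span.kind == "posttilt":
            base[mask] += params.aftereffect_deg

    half_off = params.interocular_offset / 2.0
    left = base + half_off + rng.normal(0.0, params.noise_sd, n)
    right = base - half_off + rng.normal(0.0, params.noise_sd, n)
    return TorsionTrace(time_s=time_s, left_deg=left, right_deg=right)


def reference_to_baseline(
    trace: TorsionTrace, baseline_window: tuple[float, float]
) -> TorsionTrace:
    """Subtract each eye's mean over the baseline window from its series.

    Idempotent and invariant to constant shifts of the raw trace.
    """
    t0, t1 = baseline_window
    mask = (trace.time_s >= t0) & (trace.time_s <= t1)
    if not mask.any():
        raise InvalidInputError("baseline window contains no samples")
    return TorsionTrace(
        time_s=trace.time_s.copy(),
        left_deg=trace.left_deg - trace.left_deg[mask].mean(),
        right_deg=trace.right_deg - trace.right_deg[mask].mean(),
    )


def trial_torsion(trace: TorsionTrace, window: tuple[float, float]) -> float:
    """Mean binocular torsion over one trial window [onset, response]."""
    t0, t1 = window
    mask = (trace.time_s >= t0) & (trace.time_s <= t1)
    if not mask.any():
        raise InvalidInputError("trial window contains no samples")
    return float(trace.binocular()[mask].mean())


def per_trial_torsion(trace: TorsionTrace, log: pd.DataFrame) -> np.ndarray:
    """Vectorized ``trial_torsion`` for every answered trial of a log.

    Windows span line onset to response.  Returns an array aligned with the
    answered rows of ``log`` (missed rows are skipped by the caller).
    """
    bino = trace.binocular()
    csum = np.concatenate([[0.0], np.cumsum(bino)])
    onsets = log["onset_time_s"].to_numpy()
    ends = onsets + log["reaction_time_ms"].to_numpy() / 1000.0
    i0 = np.searchsorted(trace.time_s, onsets, side="left")
    i1 = np.searchsorted(trace.time_s, ends, side="right")
    counts = i1 - i0
    if (counts <= 0).any():
        raise InvalidInputError("a trial window contains no torsion samples")
    return (csum[i1] - csum[i0]) / counts
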