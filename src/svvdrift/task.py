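"""Adaptive subjective-visual-vertical (SVV) 2AFC paradigm.

A session is a fixed sequence of head-position segments (default: 100 trials
upright, 500 tilted, 150 upright again, with a 30-s pause whenever the head
moves).  Within a segment, trials run in blocks of ten: five line deviations
drawn uniformly from the current probing range, each shown once radiating
into the upper and once into the lower hemifield, in shuffled order.  After
every completed block the range re-centers on the SVV estimated from the
last 30 answered trials and its amplitude halves, from the full 360 deg down
to a 10 deg floor, so the paradigm tracks a drifting point of subjective
equality without assuming one.  Missed trials are re-queued within their
block so every planned angle is answered exactly once.  Every head-position
change resets the range to 360 deg.

Given a seeded generator the whole loop is deterministic: identical seeds
replay bit-identical trial logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, InsufficientDataError, InvalidInputError
from .observer import VirtualObserver, apply_scenario, initial_state, simulate_response

__all__ = [
    "SessionProtocol",
    "AngleRange",
    "BlockPlan",
    "plan_block",
    "mini_svv_estimate",
    "update_range",
    "run_session",
    "segment_kind",
]

#: Floor of the probing-range amplitude, deg (+-5 around the running center).
AMPLITUDE_FLOOR = 10.0
#: Trials per block: 5 deviations x 2 hemifields.
BLOCK_SIZE = 10
#: Answered trials feeding each running SVV estimate.
ESTIMATE_WINDOW = 30
#: Dead time after a missed trial before the next one starts, s.
MISS_RESUME_S = 0.5

TRIAL_COLUMNS = [
    "session_id",
    "subject_id",
    "trial_index",
    "segment_id",
    "block_index",
    "head_angle_deg",
    "hemifield",
    "deviation_deg",
    "ray_angle_deg",
    "response",
    "reaction_time_ms",
    "onset_time_s",
]


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered head-position segments and the trial timing constants."""

    segments: tuple = ((0.0, 100), (20.0, 500), (0.0, 150))
    pause_s: float = 30.0
    fixation_s: float = 1.0
    line_min_s: float = 0.3
    line_max_s: float = 1.5
    intertrial_s: float = 0.2  # button press -> next fixation onset

    @property
    def expected_trial_s(self) -> float:
        """Nominal trial duration at a given mean reaction time is
        ``fixation_s + rt + intertrial_s``; this is the rt-free part."""
        return self.fixation_s + self.intertrial_s

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("protocol needs at least one segment")
        for angle, n in self.segments:
            if not np.isfinite(angle):
                raise ConfigurationError("segment head angle must be finite")
            if n <= 0 or n % BLOCK_SIZE != 0:
                raise ConfigurationError(
                    f"segment trial count must be a positive multiple of {BLOCK_SIZE}"
                )

    @property
    def n_trials(self) -> int:
        return sum(n for _, n in self.segments)

    @classmethod
    def for_tilt(cls, direction: str, tilt_angle: float = 20.0) -> "SessionProtocol":
        """Default 750-trial protocol with a left or right 20 deg tilt."""
        sign = {"left": -1.0, "right": 1.0}.get(direction)
        if sign is None:
            raise ConfigurationError("direction must be 'left' or 'right'")
        return cls(segments=((0.0, 100), (sign * tilt_angle, 500), (0.0, 150)))


def segment_kind(protocol: SessionProtocol, segment_id: int) -> str:
    """'baseline' / 'tilt' / 'posttilt' label for one protocol segment."""
    angle = protocol.segments[segment_id][0]
    if angle != 0.0:
        return "tilt"
    if any(a != 0.0 for a, _ in protocol.segments[:segment_id]):
        return "posttilt"
    return "baseline"


@dataclass(frozen=True)
class AngleRange:
    """Current probing range: ``center +- amplitude/2``, and the block index."""

    center: float
    amplitude: float
    block_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude <= 360.0):
            raise ConfigurationError("amplitude must lie in (0, 360]")
        if not np.isfinite(self.center):
            raise ConfigurationError("center must be finite")


@dataclass(frozen=True)
class BlockPlan:
    """Ten planned presentations: 5 deviations x {top, bottom}, shuffled."""

    deviations: tuple
    order: tuple  # of (deviation, hemifield) pairs in presentation order


def _fold_deviation(angle: float) -> float:
    """Reduce a raw angle to the line's deviation in (-90, 90].

    A luminous line is the same stimulus rotated by 180 deg, so angles are
    taken modulo 180 and re-centered on the gravitational meridian.
    """
    d = (angle + 90.0) % 180.0 - 90.0
    return 90.0 if d == -90.0 else d


def ray_angle(deviation: float, hemifield: str) -> float:
    """Ray orientation in (-180, 180] (0 = up) for a deviation + hemifield."""
    if hemifield == "top":
        return deviation
    r = deviation - 180.0
    return r + 360.0 if r <= -180.0 else r


def plan_block(range_: AngleRange, rng: np.random.Generator) -> BlockPlan:
    """Draw one block: 5 i.i.d. uniform deviations from the range, both
    hemifields each, in a seeded shuffled presentation order."""
    half = range_.amplitude / 2.0
    raw = rng.uniform(range_.center - half, range_.center + half, size=5)
    deviations = tuple(_fold_deviation(float(a)) for a in raw)
    pairs = [(d, h) for d in deviations for h in ("top", "bottom")]
    order = tuple(pairs[i] for i in rng.permutation(len(pairs)))
    return BlockPlan(deviations=deviations, order=order)


def mini_svv_estimate(deviations, responses_right) -> float:
    """Running SVV estimate from up to 30 answered trials.

    Primary estimator: logistic GLM point of subjective equality.  When the
    responses are perfectly separable (common while the probing range is
    still wide and the psychometric slope steep) or the GLM does not
    converge, fall back to the midpoint between the largest deviation
    answered "left" and the smallest answered "right"; unanimous responses
    yield the presented-range edge nearest the implied PSE.
    """
    dev = np.asarray(deviations, dtype=float)
    resp = np.asarray(responses_right, dtype=bool)
    if dev.size < BLOCK_SIZE:
        raise InsufficientDataError("need at least 10 answered trials")

    lefts = dev[~resp]
    rights = dev[resp]
    if lefts.size == 0:  # all "right": PSE below every presented deviation
        return float(rights.min())
    if rights.size == 0:  # all "left": PSE above every presented deviation
        return float(lefts.max())
    midpoint = float((lefts.max() + rights.min()) / 2.0)
    if lefts.max() < rights.min():  # perfectly separable
        return midpoint

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                resp.astype(float), sm.add_constant(dev), family=sm.families.Binomial()
            ).fit(maxiter=50)
        intercept, slope = res.params
        pse = -intercept / slope
        if res.converged and slope > 0 and np.isfinite(pse) and abs(pse) <= 90.0:
            return float(pse)
    except Exception:
        pass
    return midpoint


def _next_range(center: float, range_: AngleRange) -> AngleRange:
    return AngleRange(
        center=center,
        amplitude=max(range_.amplitude / 2.0, AMPLITUDE_FLOOR),
        block_index=range_.block_index + 1,
    )


def update_range(history: pd.DataFrame, range_: AngleRange) -> AngleRange:
    """Re-center on the last 30 answered trials of the current (= last)
    segment and halve the amplitude down to the 10 deg floor."""
    seg = history[history["segment_id"] == history["segment_id"].iloc[-1]]
    answered = seg[seg["response"] != "missed"].tail(ESTIMATE_WINDOW)
    center = mini_svv_estimate(
        answered["deviation_deg"].to_numpy(),
        (answered["response"] == "right").to_numpy(),
    )
    return _next_range(center, range_)


def run_session(
    observer: VirtualObserver,
    protocol: SessionProtocol = SessionProtocol(),
    rng: np.random.Generator | None = None,
    miss_prob: float = 0.005,
    session_id: str = "session",
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Closed-loop simulation of one full session.

    Per trial: 1 s fixation, line onset (the observer's scenario state is
    advanced to that instant), a Bernoulli response after a log-normal
    reaction time.  Trials missed (no response within 1.5 s) are logged and
    re-queued at the end of the block's remaining order.  Returns one row
    per presentation; answered rows total ``protocol.n_trials``.
    """
    if rng is None:
        raise ConfigurationError("run_session requires a seeded generator")
    if not (0.0 <= miss_prob < 1.0):
        raise ConfigurationError("miss_prob must lie in [0, 1)")

    rows: list[dict] = []
    t = 0.0
    index = 0
    state = initial_state(observer.params, protocol.segments[0][0], observer.schedule)

    for seg_id, (angle, n_trials) in enumerate(protocol.segments):
        if not np.isfinite(angle):
            raise ConfigurationError("non-finite head angle")
        kind = segment_kind(protocol, seg_id)
        seg_params = observer.params_for(kind)
        rt_mean = observer.rt_mean_for(kind)
        if seg_id > 0:
            t += protocol.pause_s  # head moves; paradigm pauses and resets
        range_ = AngleRange(center=0.0, amplitude=360.0, block_index=0)
        seg_devs: list[float] = []
        seg_resps: list[bool] = []

        for _ in range(n_trials // BLOCK_SIZE):
            plan = plan_block(range_, rng)
            queue = list(plan.order)
            while queue:
                deviation, hemifield = queue.pop(0)
                onset = t + protocol.fixation_s
                state = apply_scenario(
                    state, observer.schedule, seg_params, onset, kind, angle
                )
                index += 1
                if rng.random() < miss_prob:
                    queue.append((deviation, hemifield))
                    response, rt = "missed", np.nan
                    t = onset + protocol.line_max_s + MISS_RESUME_S + protocol.intertrial_s
                else:
                    response, rt = simulate_response(
                        state, seg_params, deviation, rng, rt_mean, observer.rt_shape
                    )
                    seg_devs.append(deviation)
                    seg_resps.append(response == "right")
                    t = onset + rt / 1000.0 + protocol.intertrial_s
                rows.append(
                    {
                        "session_id": session_id,
                        "subject_id": subject_id,
                        "trial_index": index,
                        "segment_id": seg_id,
                        "block_index": range_.block_index,
                        "head_angle_deg": angle,
                        "hemifield": hemifield,
                        "deviation_deg": deviation,
                        "ray_angle_deg": ray_angle(deviation, hemifield),
                        "response": response,
                        "reaction_time_ms": rt,
                        "onset_time_s": onset,
                    }
                )
            center = mini_svv_estimate(
                seg_devs[-ESTIMATE_WINDOW:], seg_resps[-ESTIMATE_WINDOW:]
            )
            range_ = _next_range(center, range_)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
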