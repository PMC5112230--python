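"""Synthetic cohort: 12 virtual subjects, two tilt sessions each.

Each subject's per-condition behaviour is drawn from Gaussian group
distributions whose means are the study-level group values and whose
between-subject SDs are the printed SEMs scaled by sqrt(12).  The draws fix
a *planted truth* per session — baseline SVV, initial tilt bias, SVV drift
per 500 trials, SVV aftereffect, counterroll gain, torsion drift and
aftereffect, per-condition precision and reaction times — and the generator
then solves for the sensory-bias schedule of the Bayesian observer that
realizes exactly that SVV trajectory:

* the planted SVV path during tilt is linear in answered-trial index,
  anchored so the first analysis window (trials 51-150) recovers the
  planted initial bias;
* the bias rate is converted from per-500-trials to per-minute using the
  expected trial duration (fixation + mean reaction time), making the drift
  land on the per-trial scale the analysis reports;
* the post-tilt bias is a persistent residual chosen so post-tilt SVV
  equals baseline + planted aftereffect.

SVV and torsion draws are independent by default, as are drift and
aftereffect (coupling knobs exist for power experiments), so planted
correlations are null and any pipeline-detected association is noise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import GroupStats, pool_group, summarize_session
from .errors import ConfigurationError
from .observer import ObserverParams, ScenarioSchedule, VirtualObserver, bayes_weight, svv_error
from .task import SessionProtocol, run_session
from .torsion import TorsionParams, TorsionTrace, generate_trace, timeline_from_log

__all__ = [
    "CohortConfig",
    "SubjectSpec",
    "StudyBundle",
    "sample_cohort",
    "build_session_inputs",
    "simulate_study",
    "summarize",
]

logger = logging.getLogger(__name__)

_LN3 = math.log(3.0)
CONDITIONS = ("left", "right")


@dataclass(frozen=True)
class CohortConfig:
    """Group-level generator parameters: (mean, between-subject SD) pairs.

    Between-subject SDs equal the group SEM times sqrt(n_subjects) wherever
    a SEM is available; precision and reaction time are drawn per condition
    segment.  Coupling knobs are correlations in [0, 1]; at the default 0
    the flagged pairs are drawn independently.
    """

    n_subjects: int = 12
    tilt_angle: float = 20.0
    baseline_svv: tuple = (-0.2, 2.08)
    initial_svv: dict = field(
        default_factory=lambda: {"left": (0.2, 5.20), "right": (-2.6, 4.50)}
    )
    svv_drift: dict = field(
        default_factory=lambda: {"left": (-5.4, 4.85), "right": (2.2, 7.27)}
    )
    svv_aftereffect: dict = field(
        default_factory=lambda: {"left": (-3.9, 2.08), "right": (2.55, 3.46)}
    )
    torsion_gain: tuple = (0.20, 0.069)
    torsion_drift: dict = field(
        default_factory=lambda: {"left": (-0.8, 1.04), "right": (0.6, 0.69)}
    )
    torsion_aftereffect: dict = field(
        default_factory=lambda: {"left": (-0.2, 1.04), "right": (0.2, 1.04)}
    )
    precision: dict = field(
        default_factory=lambda: {
            "baseline": (0.7, 0.346),
            "tilt": (2.0, 1.04),
            "posttilt": (1.3, 0.346),
        }
    )
    rt_mean_ms: dict = field(
        default_factory=lambda: {
            "baseline": (640.0, 97.0),
            "tilt": (686.0, 87.0),
            "posttilt": (661.0, 104.0),
        }
    )
    observer: ObserverParams = ObserverParams()
    miss_prob: float = 0.005
    torsion_noise_sd: float = 0.08
    interocular_offset: float = 0.3
    couple_drift_aftereffect: float = 0.0
    couple_svv_torsion: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for knob in (self.couple_drift_aftereffect, self.couple_svv_torsion):
            if not (0.0 <= knob <= 1.0):
                raise ConfigurationError("coupling knobs must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["observer"] = asdict(self.observer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverParams(**d["observer"])
        for key in ("baseline_svv", "torsion_gain"):
            if key in d:
                d[key] = tuple(d[key])
        for key in (
            "initial_svv",
            "svv_drift",
            "svv_aftereffect",
            "torsion_drift",
            "torsion_aftereffect",
            "precision",
            "rt_mean_ms",
        ):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass(frozen=True)
class SubjectSpec:
    """One virtual subject: id, seed material, and planted per-condition truth."""

    subject_id: str
    index: int
    condition_order: tuple
    planted: dict  # condition -> {metric: value}


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Gaussian draw redrawn (then clipped) into [lo, hi]; redraws logged."""
    for attempt in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            if attempt:
                logger.debug("redrew %d time(s) for N(%.3g, %.3g)", attempt, mean, sd)
            return float(v)
    logger.warning("clipping draw from N(%.3g, %.3g) into [%g, %g]", mean, sd, lo, hi)
    return float(min(max(mean, lo), hi))


def _coupled_pair(
    rng: np.random.Generator, a: tuple, b: tuple, r: float
) -> tuple[float, float]:
    """Two Gaussian draws with correlation r (independent at r = 0)."""
    z1, z2 = rng.standard_normal(2)
    z_b = r * z1 + math.sqrt(max(1.0 - r * r, 0.0)) * z2
    return a[0] + a[1] * z1, b[0] + b[1] * z_b


def sample_cohort(config: CohortConfig, seed: int) -> list[SubjectSpec]:
    """Draw the planted truth for every subject and condition.

    Reproducible: (config, seed) -> identical cohort.  Session condition
    order is randomized per subject, as in the study.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    specs = []
    for i in range(config.n_subjects):
        order = ("left", "right") if rng.random() < 0.5 else ("right", "left")
        planted: dict = {}
        for cond in CONDITIONS:
            drift, after = _coupled_pair(
                rng,
                config.svv_drift[cond],
                config.svv_aftereffect[cond],
                config.couple_drift_aftereffect,
            )
            tdrift_mean, tdrift_sd = config.torsion_drift[cond]
            drift_mean, drift_sd = config.svv_drift[cond]
            svv_z = (drift - drift_mean) / drift_sd if drift_sd > 0 else 0.0
            r = config.couple_svv_torsion
            t_z = r * svv_z + math.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal()
            planted[cond] = {
                "baseline_svv": rng.normal(*config.baseline_svv),
                "initial_svv": rng.normal(*config.initial_svv[cond]),
                "svv_drift": float(drift),
                "svv_aftereffect": float(after),
                "torsion_gain": _trunc_normal(rng, *config.torsion_gain, 0.02, 0.50),
                "torsion_drift": float(tdrift_mean + tdrift_sd * t_z),
                "torsion_aftereffect": rng.normal(*config.torsion_aftereffect[cond]),
                "precision_baseline": _trunc_normal(
                    rng, *config.precision["baseline"], 0.15, 5.0
                ),
                "precision_tilt": _trunc_normal(rng, *config.precision["tilt"], 0.3, 8.0),
                "precision_posttilt": _trunc_normal(
                    rng, *config.precision["posttilt"], 0.2, 6.0
                ),
                "rt_baseline": _trunc_normal(rng, *config.rt_mean_ms["baseline"], 400, 1200),
                "rt_tilt": _trunc_normal(rng, *config.rt_mean_ms["tilt"], 400, 1200),
                "rt_posttilt": _trunc_normal(rng, *config.rt_mean_ms["posttilt"], 400, 1200),
            }
        specs.append(
            SubjectSpec(
                subject_id=f"S{i + 1:02d}", index=i, condition_order=order, planted=planted
            )
        )
    return specs


def build_session_inputs(
    config: CohortConfig, spec: SubjectSpec, condition: str
) -> tuple[VirtualObserver, SessionProtocol, TorsionParams]:
    """Solve the observer schedule that realizes one session's planted truth.

    The sensory-bias channel is anchored per segment by inverting
    ``mu = mu_static(H) - (1 - w)·b`` at the planted SVV values; the tilt
    ramp slope converts the planted per-500-trials drift into deg/min via
    the subject's expected trial duration.
    """
    p = spec.planted[condition]
    params = config.observer
    protocol = SessionProtocol.for_tilt(condition, config.tilt_angle)
    tilt_angle = protocol.segments[1][0]

    w0 = bayes_weight(params, 0.0)
    w_t = bayes_weight(params, tilt_angle)
    static0 = svv_error(params, 0.0)
    static_t = svv_error(params, tilt_angle)

    # planted SVV path during tilt, in answered-trial index tau (1-based):
    # mu(tau) = initial + drift * (tau - 100.5) / 500, so the first analysis
    # window (trials 51-150, center 100.5) recovers the planted initial bias.
    drift = p["svv_drift"] / 500.0  # deg per answered trial
    mu_tilt_onset = p["initial_svv"] - drift * 99.5
    trial_s = protocol.expected_trial_s + p["rt_tilt"] / 1000.0
    rate_bias = -(drift / trial_s) * 60.0 / (1.0 - w_t)  # deg/min of bias

    mu_post = p["baseline_svv"] + p["svv_aftereffect"]
    schedule = ScenarioSchedule(
        kind="sensory_drift",
        form="linear",
        tilt_rate=rate_bias,
        aftereffect_decay=math.inf,
        bias_baseline=(static0 - p["baseline_svv"]) / (1.0 - w0),
        bias_tilt_onset=(static_t - mu_tilt_onset) / (1.0 - w_t),
        bias_posttilt=(static0 - mu_post) / (1.0 - w0),
    )
    observer = VirtualObserver(
        params=params,
        schedule=schedule,
        decision_scale_by_segment={
            "baseline": p["precision_baseline"] / _LN3,
            "tilt": p["precision_tilt"] / _LN3,
            "posttilt": p["precision_posttilt"] / _LN3,
        },
        rt_mean_ms_by_segment={
            "baseline": p["rt_baseline"],
            "tilt": p["rt_tilt"],
            "posttilt": p["rt_posttilt"],
        },
    )
    torsion = TorsionParams(
        counterroll_gain=p["torsion_gain"],
        drift_per_500trials=p["torsion_drift"],
        aftereffect_deg=p["torsion_aftereffect"],
        noise_sd=config.torsion_noise_sd,
        interocular_offset=config.interocular_offset,
    )
    return observer, protocol, torsion


@dataclass
class Session:
    log: pd.DataFrame
    trace: TorsionTrace
    planted: dict


@dataclass
class StudyBundle:
    """Self-describing study output: config, seed, and all sessions."""

    config: CohortConfig
    seed: int
    specs: list
    sessions: dict  # (subject_id, condition) -> Session

    def write_dir(self, out: Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "condition_order": list(s.condition_order),
                    "planted": s.planted,
                }
                for s in self.specs
            ],
            "sessions": [],
        }
        for (sub, cond), sess in self.sessions.items():
            log_name = f"{sub}_{cond}_trials.csv"
            tor_name = f"{sub}_{cond}_torsion.csv"
            sess.log.to_csv(out / log_name, index=False, float_format="%.6f")
            sess.trace.to_frame().to_csv(out / tor_name, index=False, float_format="%.4f")
            manifest["sessions"].append(
                {"subject_id": sub, "condition": cond, "trials": log_name, "torsion": tor_name}
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def simulate_study(
    specs: list[SubjectSpec],
    config: CohortConfig,
    seed: int,
    conditions: tuple = CONDITIONS,
) -> StudyBundle:
    """Replay the whole study: every subject, every requested condition.

    Per-session RNG streams are spawned from (seed, subject index,
    condition index), so any subset of sessions is bit-reproducible.
    """
    sessions = {}
    for spec in specs:
        for cond in spec.condition_order:
            if cond not in conditions:
                continue
            observer, protocol, torsion_params = build_session_inputs(config, spec, cond)
            cond_idx = CONDITIONS.index(cond)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 1 + spec.index, cond_idx])
            )
            log = run_session(
                observer,
                protocol,
                rng,
                miss_prob=config.miss_prob,
                session_id=f"{spec.subject_id}_{cond}",
                subject_id=spec.subject_id,
            )
            trace = generate_trace(torsion_params, timeline_from_log(log), rng)
            sessions[(spec.subject_id, cond)] = Session(
                log=log, trace=trace, planted=spec.planted[cond]
            )
    return StudyBundle(config=config, seed=seed, specs=specs, sessions=sessions)


def summarize(bundle: StudyBundle) -> dict:
    """Run the analysis pipeline on every session and pool the cohort.

    Returns per-subject summaries, group statistics, and a recovery table
    placing each pipeline group estimate next to the planted truth (the
    mean of the planted per-subject draws) and the configured group mean.
    """
    per_subject: dict[str, dict] = {}
    for (sub, cond), sess in bundle.sessions.items():
        summary = summarize_session(sess.log, sess.trace)
        summary.pop("series")
        per_subject.setdefault(sub, {"subject_id": sub})[cond] = summary

    summaries = list(per_subject.values())
    group: GroupStats | None = None
    if sum(1 for s in summaries if "left" in s and "right" in s) >= 3:
        group = pool_group(summaries)

    recovery = {}
    metric_map = {
        "baseline_svv": "baseline_svv",
        "initial_svv": "initial_svv",
        "drift_svv": "svv_drift",
        "aftereffect_svv": "svv_aftereffect",
        "drift_torsion": "torsion_drift",
        "aftereffect_torsion": "torsion_aftereffect",
        "precision_baseline": "precision_baseline",
        "precision_tilt": "precision_tilt",
        "counterroll_gain": "torsion_gain",
    }
    conditions = sorted({c for (_, c) in bundle.sessions})
    for cond in conditions:
        sess_list = [s for (key, s) in bundle.sessions.items() if key[1] == cond]
        block = {}
        for est_name, planted_name in metric_map.items():
            ests = [
                s[cond][est_name]
                for s in summaries
                if cond in s and est_name in s[cond] and np.isfinite(s[cond][est_name])
            ]
            planted = [sess.planted[planted_name] for sess in sess_list]
            if not ests:
                continue
            block[est_name] = {
                "estimate_mean": float(np.mean(ests)),
                "estimate_sem": float(np.std(ests, ddof=1) / math.sqrt(len(ests)))
                if len(ests) > 1
                else float("nan"),
                "planted_mean": float(np.mean(planted)),
                "n": len(ests),
            }
        recovery[cond] = block

    return {
        "per_subject": summaries,
        "group": group.to_dict() if group is not None else None,
        "recovery": recovery,
    }
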