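"""Psychometric fitting and the sliding-window drift/aftereffect pipeline.

The raw material is a 2AFC trial log (line deviation -> left/right response)
and, optionally, a time-aligned binocular torsion trace.  The pipeline:

1. fits a logistic psychometric function per window of 100 answered trials,
   advancing in steps of 50 within each head-position segment, after
   discarding the segment's first 50 trials (the probing range is still too
   wide there for a reliable estimate);
2. averages the per-trial binocular torsion over the same windows;
3. regresses the windowed SVV and torsion series on trial index (primary,
   reported per 500 trials) and on time (reported per minute) to estimate
   drift during the tilt;
4. takes the post-tilt windowed value minus the pre-tilt baseline as the
   aftereffect;
5. pools per-subject summaries into group means +- SEM, paired t-tests and
   Spearman correlations (after sign-flip averaging of the two tilt
   directions), with a flat 0.01 significance threshold.

The SVV of a fit is its point of subjective equality (50 % point); the
precision is the 75 %-50 % distance, which for a logistic with slope ``b``
is exactly ``ln 3 / b``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import AlignmentError, InsufficientDataError, InvalidInputError
from .torsion import TorsionTrace, per_trial_torsion, reference_to_baseline, timeline_from_log

__all__ = [
    "PsychometricFit",
    "DriftEstimate",
    "GroupStats",
    "fit_psychometric",
    "window_spans",
    "sliding_series",
    "fit_drift",
    "compute_aftereffect",
    "summarize_session",
    "pool_group",
    "ALPHA",
]

_LN3 = math.log(3.0)

#: Window geometry of the sliding analysis (answered trials, within segment).
WINDOW = 100
STEP = 50
DISCARD = 50

#: Flat significance threshold applied as a label; raw p-values are reported.
ALPHA = 0.01

#: Ridge strength of the separation fallback (sklearn C = inverse strength).
_RIDGE_C = 10.0


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic psychometric fit: PSE, precision (= ln3/slope), slope."""

    pse: float
    precision: float
    slope: float
    n: int
    converged: bool


@dataclass(frozen=True)
class DriftEstimate:
    """Linear drift of a windowed series, on both axes the study reports."""

    slope_per_500_trials: float
    slope_per_min: float
    intercept: float
    r2: float
    n: int


@dataclass
class GroupStats:
    """Condition means +- SEM, paired tests and Spearman correlations."""

    n_subjects: int
    condition_means: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "condition_means": self.condition_means,
            "tests": self.tests,
            "correlations": self.correlations,
        }


def _edge_estimate(dev: np.ndarray, resp: np.ndarray) -> float:
    """PSE stand-in for unanimous responses: the presented-range edge
    nearest the implied PSE (below all deviations if all 'right', above
    if all 'left')."""
    return float(dev.min()) if resp.all() else float(dev.max())


def fit_psychometric(deviations, responses_right) -> PsychometricFit:
    """Binomial-logit regression of response-is-right on line deviation.

    Needs >= 30 answered trials with >= 2 distinct deviations.  On perfect
    separation or non-convergence the fit is re-done with a ridge-penalized
    logistic so every window still reports a value; ``converged`` stays
    False for auditing.  Unanimous responses fall back to the range-edge
    rule and carry no slope.
    """
    dev = np.asarray(deviations, dtype=float)
    resp = np.asarray(responses_right, dtype=bool)
    if dev.size < 30:
        raise InsufficientDataError("need at least 30 answered trials")
    if np.unique(dev).size < 2:
        raise InsufficientDataError("need at least 2 distinct deviations")

    if resp.all() or (~resp).all():
        return PsychometricFit(
            pse=_edge_estimate(dev, resp),
            precision=float("nan"),
            slope=float("nan"),
            n=dev.size,
            converged=False,
        )

    lefts, rights = dev[~resp], dev[resp]
    separable = lefts.max() < rights.min()
    if not separable:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    resp.astype(float),
                    sm.add_constant(dev),
                    family=sm.families.Binomial(),
                ).fit(maxiter=100)
            intercept, slope = res.params
            pse = -intercept / slope
            if (
                res.converged
                and slope > 0
                and np.isfinite(pse)
                and np.isfinite(slope)
                and abs(pse) <= 180.0
            ):
                return PsychometricFit(
                    pse=float(pse),
                    precision=float(_LN3 / slope),
                    slope=float(slope),
                    n=dev.size,
                    converged=True,
                )
        except Exception:
            pass

    clf = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=1000)
    clf.fit(dev.reshape(-1, 1), resp.astype(int))
    slope = float(clf.coef_[0, 0])
    intercept = float(clf.intercept_[0])
    if slope <= 0:
        midpoint = (lefts.max() + rights.min()) / 2.0
        return PsychometricFit(float(midpoint), float("nan"), slope, dev.size, False)
    return PsychometricFit(
        pse=-intercept / slope,
        precision=_LN3 / slope,
        slope=slope,
        n=dev.size,
        converged=False,
    )


def window_spans(n_answered: int, window: int = WINDOW, step: int = STEP,
                 discard: int = DISCARD) -> list[tuple[int, int]]:
    """1-based within-segment spans of the sliding windows.

    First window starts right after the discarded trials; a window is
    emitted only if a full ``window`` trials fit inside the segment.
    """
    spans = []
    start = discard + 1
    while start + window - 1 <= n_answered:
        spans.append((start, start + window - 1))
        start += step
    return spans


def _segment_kinds(log: pd.DataFrame) -> dict[int, str]:
    kinds: dict[int, str] = {}
    saw_tilt = False
    for seg_id in sorted(log["segment_id"].unique()):
        angle = float(log.loc[log["segment_id"] == seg_id, "head_angle_deg"].iloc[0])
        if angle != 0.0:
            kinds[seg_id] = "tilt"
            saw_tilt = True
        else:
            kinds[seg_id] = "posttilt" if saw_tilt else "baseline"
    return kinds


def _referenced_torsion(log: pd.DataFrame, trace: TorsionTrace) -> TorsionTrace:
    """Reference the trace to the pre-tilt upright recording of this log."""
    timeline = timeline_from_log(log)
    base = next((s for s in timeline if s.kind == "baseline"), timeline[0])
    return reference_to_baseline(trace, (base.t_start, base.t_end))


def _answered(log: pd.DataFrame) -> pd.DataFrame:
    return log[log["response"] != "missed"]


def sliding_series(log: pd.DataFrame, trace: TorsionTrace | None = None) -> pd.DataFrame:
    """Windowed SVV (+ torsion) series; one row per window, never crossing
    a segment boundary.

    Columns: window_id, segment_id, segment_kind, first, last (within-
    segment answered indices), trial_mid, time_mid_s, svv_deg,
    precision_deg, converged, and torsion_deg when a trace is supplied.
    """
    answered = _answered(log).reset_index(drop=True)
    kinds = _segment_kinds(log)

    torsion_vals = None
    if trace is not None:
        ref = _referenced_torsion(log, trace)
        try:
            torsion_vals = per_trial_torsion(ref, answered)
        except InvalidInputError as err:
            raise AlignmentError(f"torsion trace does not cover the trial log: {err}")

    rows = []
    window_id = 0
    for seg_id in sorted(kinds):
        seg = answered[answered["segment_id"] == seg_id]
        idx = seg.index.to_numpy()
        for first, last in window_spans(len(seg)):
            sel = idx[first - 1 : last]
            sub = answered.loc[sel]
            fit = fit_psychometric(
                sub["deviation_deg"].to_numpy(),
                (sub["response"] == "right").to_numpy(),
            )
            row = {
                "window_id": window_id,
                "segment_id": seg_id,
                "segment_kind": kinds[seg_id],
                "first": first,
                "last": last,
                "trial_mid": (first + last) / 2.0,
                "time_mid_s": float(sub["onset_time_s"].mean()),
                "svv_deg": fit.pse,
                "precision_deg": fit.precision,
                "converged": fit.converged,
            }
            if torsion_vals is not None:
                row["torsion_deg"] = float(np.mean(torsion_vals[sel]))
            rows.append(row)
            window_id += 1
    columns = [
        "window_id",
        "segment_id",
        "segment_kind",
        "first",
        "last",
        "trial_mid",
        "time_mid_s",
        "svv_deg",
        "precision_deg",
        "converged",
    ] + (["torsion_deg"] if torsion_vals is not None else [])
    return pd.DataFrame(rows, columns=columns)


def fit_drift(series: pd.DataFrame, column: str = "svv_deg") -> DriftEstimate:
    """OLS drift of one segment's windowed series.

    Primary regression on window-center trial index (slope rescaled to per
    500 trials); a second regression on window-center time gives the
    per-minute slope.
    """
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 series points")
    y = series[column].to_numpy(dtype=float)
    by_trial = stats.linregress(series["trial_mid"].to_numpy(dtype=float), y)
    by_time = stats.linregress(series["time_mid_s"].to_numpy(dtype=float), y)
    return DriftEstimate(
        slope_per_500_trials=float(by_trial.slope * 500.0),
        slope_per_min=float(by_time.slope * 60.0),
        intercept=float(by_trial.intercept),
        r2=float(by_trial.rvalue**2),
        n=len(series),
    )


def compute_aftereffect(post_values, baseline_value: float) -> float:
    """Mean post-tilt value minus the pre-tilt baseline (same contract for
    SVV and torsion)."""
    vals = np.asarray(post_values, dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("post-tilt series is empty")
    if not np.isfinite(baseline_value):
        raise InsufficientDataError("missing baseline value")
    return float(vals.mean() - baseline_value)


def _baseline_fit(answered: pd.DataFrame) -> PsychometricFit:
    """Baseline SVV: the single 100-trial logistic fit over the segment's
    last 100 answered trials.  The 100-trial baseline segment is too short
    for the discard-50 sliding rule, so its one estimate spans the whole
    segment (the later trials dominate once the range has narrowed)."""
    if len(answered) < WINDOW:
        raise InsufficientDataError(
            f"baseline segment needs >= {WINDOW} answered trials, got {len(answered)}"
        )
    sub = answered.tail(WINDOW)
    return fit_psychometric(
        sub["deviation_deg"].to_numpy(), (sub["response"] == "right").to_numpy()
    )


def summarize_session(log: pd.DataFrame, trace: TorsionTrace | None = None) -> dict:
    """Every per-session quantity the study tabulates.

    Torsion-derived entries are omitted (not errored) when no trace is
    given.  SVV drift/aftereffect come from the sliding series; the initial
    tilt bias is the first tilt-segment window (within-segment trials
    51-150).
    """
    answered = _answered(log)
    kinds = _segment_kinds(log)
    by_kind = {k: [s for s, kk in kinds.items() if kk == k] for k in ("baseline", "tilt", "posttilt")}
    if not by_kind["baseline"]:
        raise InsufficientDataError("log has no baseline segment")

    series = sliding_series(log, trace)
    has_torsion = trace is not None

    base_seg = answered[answered["segment_id"] == by_kind["baseline"][0]]
    base_fit = _baseline_fit(base_seg)

    out: dict = {
        "baseline_svv": base_fit.pse,
        "precision_baseline": base_fit.precision,
        "n_answered": int(len(answered)),
        "series": series,
    }
    tilt_angle = 0.0
    if by_kind["tilt"]:
        tilt_angle = float(
            log.loc[log["segment_id"] == by_kind["tilt"][0], "head_angle_deg"].iloc[0]
        )
    out["tilt_angle"] = tilt_angle

    for k in ("baseline", "tilt", "posttilt"):
        segs = by_kind[k]
        if segs:
            rts = answered[answered["segment_id"].isin(segs)]["reaction_time_ms"]
            out[f"rt_mean_{k}"] = float(rts.mean())

    tilt_series = series[series["segment_kind"] == "tilt"]
    if len(tilt_series) >= 3:
        drift = fit_drift(tilt_series, "svv_deg")
        out["drift_svv"] = drift.slope_per_500_trials
        out["drift_svv_per_min"] = drift.slope_per_min
        out["initial_svv"] = float(tilt_series["svv_deg"].iloc[0])
        out["precision_tilt"] = float(tilt_series["precision_deg"].mean())

    post_series = series[series["segment_kind"] == "posttilt"]
    if len(post_series) > 0:
        out["aftereffect_svv"] = compute_aftereffect(
            post_series["svv_deg"].to_numpy(), base_fit.pse
        )
        out["precision_posttilt"] = float(post_series["precision_deg"].mean())

    if has_torsion:
        ref = _referenced_torsion(log, trace)
        base_torsion = float(per_trial_torsion(ref, base_seg).mean())
        out["baseline_torsion"] = base_torsion
        if len(tilt_series) >= 3:
            tdrift = fit_drift(tilt_series, "torsion_deg")
            out["drift_torsion"] = tdrift.slope_per_500_trials
            out["drift_torsion_per_min"] = tdrift.slope_per_min
            out["initial_torsion"] = float(tilt_series["torsion_deg"].iloc[0])
            if tilt_angle != 0.0:
                out["counterroll_gain"] = -out["initial_torsion"] / tilt_angle
        if len(post_series) > 0:
            out["aftereffect_torsion"] = compute_aftereffect(
                post_series["torsion_deg"].to_numpy(), base_torsion
            )
    return out


_POOLED_METRICS = (
    "baseline_svv",
    "initial_svv",
    "drift_svv",
    "drift_svv_per_min",
    "aftereffect_svv",
    "drift_torsion",
    "drift_torsion_per_min",
    "aftereffect_torsion",
    "precision_baseline",
    "precision_tilt",
    "precision_posttilt",
    "counterroll_gain",
    "rt_mean_baseline",
    "rt_mean_tilt",
    "rt_mean_posttilt",
)

#: Metrics whose sign follows the tilt direction; pooling across conditions
#: reverses the right-tilt values so "positive" means "toward the tilt".
_SIGNED_METRICS = {
    "initial_svv",
    "drift_svv",
    "drift_svv_per_min",
    "aftereffect_svv",
    "drift_torsion",
    "drift_torsion_per_min",
    "aftereffect_torsion",
}


def _collect(summaries: list[dict], condition: str, metric: str) -> np.ndarray:
    vals = [s[condition].get(metric) for s in summaries if condition in s]
    return np.array([v for v in vals if v is not None and np.isfinite(v)], dtype=float)


def _mean_sem(vals: np.ndarray) -> dict:
    n = vals.size
    out = {"mean": float(vals.mean()) if n else float("nan"), "n": int(n)}
    out["sem"] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return out


def _paired(summaries: list[dict], metric: str, flip_right: bool):
    pairs = []
    for s in summaries:
        if "left" not in s or "right" not in s:
            continue
        a, b = s["left"].get(metric), s["right"].get(metric)
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            continue
        pairs.append((a, -b if flip_right else b))
    return np.array(pairs, dtype=float)


def _ttest_label(t: float, p: float, n: int, degenerate: bool = False) -> dict:
    return {
        "t": float(t),
        "p": float(p),
        "n": int(n),
        "significant": bool(np.isfinite(p) and p < ALPHA),
        "degenerate": bool(degenerate),
    }


def _safe_ttest_rel(a: np.ndarray, b: np.ndarray) -> dict:
    d = a - b
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        return _ttest_label(float("nan"), float("nan"), d.size, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return _ttest_label(t, p, d.size)


def _safe_ttest_1samp(x: np.ndarray) -> dict:
    if x.size < 2 or np.allclose(x.std(ddof=1), 0.0):
        return _ttest_label(float("nan"), float("nan"), x.size, degenerate=True)
    t, p = stats.ttest_1samp(x, 0.0)
    return _ttest_label(t, p, x.size)


def pool_group(summaries: list[dict]) -> GroupStats:
    """Group statistics over per-subject session summaries.

    ``summaries`` holds one dict per subject with ``"left"`` / ``"right"``
    session summaries (from :func:`summarize_session`).  Pooled per-subject
    values average the left value with the sign-reversed right value, so
    correlations are computed once per subject in a common left-tilt frame.
    """
    complete = [s for s in summaries if "left" in s and "right" in s]
    if len(complete) < 3:
        raise InsufficientDataError("need at least 3 subjects with both conditions")

    gs = GroupStats(n_subjects=len(complete))
    for metric in _POOLED_METRICS:
        entry = {}
        for cond in ("left", "right"):
            vals = _collect(summaries, cond, metric)
            if vals.size:
                entry[cond] = _mean_sem(vals)
        if metric in _SIGNED_METRICS:
            pairs = _paired(complete, metric, flip_right=True)
            if pairs.size:
                pooled = pairs.mean(axis=1)
                entry["pooled"] = _mean_sem(pooled)
        if entry:
            gs.condition_means[metric] = entry

    for metric in ("drift_svv", "aftereffect_svv", "drift_torsion", "aftereffect_torsion"):
        pairs = _paired(complete, metric, flip_right=True)
        if pairs.shape[0] >= 3:
            # symmetry: left vs sign-reversed right; zero test on the pooled value
            gs.tests[f"{metric}_symmetry"] = _safe_ttest_rel(pairs[:, 0], pairs[:, 1])
            gs.tests[f"{metric}_vs_zero"] = _safe_ttest_1samp(pairs.mean(axis=1))

    base = _paired(complete, "baseline_svv", flip_right=False)
    if base.shape[0] >= 3:
        gs.tests["baseline_svv_left_vs_right"] = _safe_ttest_rel(base[:, 0], base[:, 1])

    def _pooled_vec(metric: str) -> np.ndarray | None:
        pairs = _paired(complete, metric, flip_right=metric in _SIGNED_METRICS)
        return pairs.mean(axis=1) if pairs.shape[0] >= 3 else None

    for name, (ma, mb) in {
        "svv_drift_vs_aftereffect": ("drift_svv", "aftereffect_svv"),
        "torsion_drift_vs_aftereffect": ("drift_torsion", "aftereffect_torsion"),
        "svv_vs_torsion_drift": ("drift_svv", "drift_torsion"),
        "svv_vs_torsion_aftereffect": ("aftereffect_svv", "aftereffect_torsion"),
    }.items():
        va, vb = _pooled_vec(ma), _pooled_vec(mb)
        if va is None or vb is None or va.size != vb.size:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(va, vb)
        gs.correlations[name] = {
            "rho": float(rho),
            "p": float(p),
            "n": int(va.size),
            "significant": bool(np.isfinite(p) and p < ALPHA),
        }
    return gs
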