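"""Feature families computed from preprocessed recordings.

Four families feed the group classification:

* **RSOT** (reference stimulus one-to-one tracking): saccade-like events
  are detected in the cleaned 20 Hz traces and matched one-to-one, by time
  (and optionally by landing position) within tolerances, against the
  same-direction stimuli of the schedule.  Match counts per stage and
  direction over their reference counts give success percentages; the
  overall score averages left/right and up/down accuracies with weights
  16 and 9 (the screen aspect ratio) over a total weight of 25.
* **CGD** (colour game detection): the binary report of the hidden
  stimulus/background colour rule.
* **Higuchi fractal dimension**: log-log slope of mean curve length
  versus delay; ~1 for smooth trends, approaching 2 for white noise.
* **Hjorth parameters**: activity (variance), mobility (first-difference
  frequency proxy), complexity (change of mobility under differentiation).

HFD and the Hjorth triple are computed per test stage and channel on the
denoised, normalized 20 Hz signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .preprocess import (
    DirectionalSegments,
    SsaConfig,
    preprocess_recording,
)
from .simulate import EogRecording
from .stimulus import (
    DIRECTIONS,
    HORIZONTAL_DIRECTIONS,
    StimulusSchedule,
    direction_counts,
)

__all__ = [
    "DetectionConfig",
    "SaccadeEvent",
    "detect_events",
    "RsotResult",
    "rsot_match",
    "success_rates",
    "weighted_success",
    "higuchi_fd",
    "HjorthTriple",
    "hjorth_params",
    "cgd_rate",
    "FeatureVector",
    "assemble_features",
    "PipelineConfig",
    "extract_features",
    "features_table",
    "round2",
]

CHANNELS = ("H", "V")


def round2(x: float) -> float:
    """Round half up to two decimals, as the summary tables report."""
    return math.floor(x * 100.0 + 0.5 + 1e-9) / 100.0


# ---------------------------------------------------------------------------
# saccade event detection


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold detector settings for saccade-like steps at 20 Hz.

    The first difference of the trace is (optionally) smoothed with a short
    moving average and thresholded at ``threshold_mad`` times its median
    absolute deviation (with an absolute floor for near-flat signals).
    Contiguous same-sign crossings form one event; same-sign events closer
    than ``refractory`` merge.  Opposite-sign event pairs closer than
    ``blink_window`` whose net level change is small relative to their
    magnitudes are discarded as blink artifacts.
    """

    smooth_window: int = 1
    threshold_mad: float = 6.0
    min_threshold: float = 0.05       # normalized units, floor for flat signals
    refractory: float = 0.15          # seconds
    reject_blinks: bool = True
    # blink flanks sit ~0.1-0.2 s apart; the window stays below the minimum
    # inter-stimulus gap so genuine opposite-saccade pairs are never eaten
    blink_window: float = 0.25        # seconds between the up and down flank
    blink_net_fraction: float = 0.4   # |net| < fraction x mean(|m1|,|m2|) -> blink
    # zero-phase filtering / SSA truncation leaves a small opposite-sign
    # overshoot right after large steps; drop it instead of calling it a saccade
    echo_window: float = 0.15         # seconds after the parent event
    echo_fraction: float = 0.3        # echo magnitude relative to the parent


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected eye movement."""

    time: float
    direction: str
    magnitude: float                  # |level change| across the event
    position_estimate: float          # channel level after the movement
    channel: str
    level_before: float = 0.0
    level_after: float = 0.0


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_events(
    x: np.ndarray,
    channel: str,
    rate: float = 20.0,
    cfg: DetectionConfig | None = None,
    t0: float = 0.0,
) -> list[SaccadeEvent]:
    """Detect saccade-like steps in one normalized channel.

    ``channel`` decides the direction labels: positive steps are "right"
    (H) or "up" (V), negative ones "left"/"down".  ``t0`` offsets reported
    event times, for signals that do not start at the recording origin.
    """
    cfg = cfg or DetectionConfig()
    if channel not in CHANNELS:
        raise ValueError(f"channel must be 'H' or 'V', got {channel!r}")
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return []
    d = np.diff(x)
    if cfg.smooth_window > 1:
        kernel = np.ones(cfg.smooth_window) / cfg.smooth_window
        d = np.convolve(d, kernel, mode="same")
    theta = max(cfg.threshold_mad * _mad(d), cfg.min_threshold)
    above = np.abs(d) >= theta
    if not above.any():
        return []

    # contiguous same-sign runs of threshold crossings -> raw events
    raw: list[tuple[int, int, int]] = []       # (start_diff_idx, end_diff_idx, sign)
    i = 0
    n = len(d)
    while i < n:
        if not above[i]:
            i += 1
            continue
        sign = 1 if d[i] > 0 else -1
        j = i
        while j + 1 < n and above[j + 1] and (d[j + 1] > 0) == (sign > 0):
            j += 1
        raw.append((i, j, sign))
        i = j + 1

    events: list[SaccadeEvent] = []
    pos_dir, neg_dir = (
        ("right", "left") if channel == "H" else ("up", "down")
    )
    for i, j, sign in raw:
        peak = i + int(np.argmax(np.abs(d[i : j + 1])))
        level_before = x[i]
        level_after = x[j + 1]
        events.append(
            SaccadeEvent(
                time=t0 + (peak + 0.5) / rate,
                direction=pos_dir if sign > 0 else neg_dir,
                magnitude=abs(level_after - level_before),
                position_estimate=float(np.clip(level_after, 0.0, 1.0)),
                channel=channel,
                level_before=float(level_before),
                level_after=float(level_after),
            )
        )

    events = _merge_refractory(events, cfg.refractory)
    events = _suppress_echoes(events, cfg)
    if cfg.reject_blinks:
        events = _reject_blinks(events, cfg)
    return [e for e in events if e.magnitude > 0]


def _suppress_echoes(
    events: list[SaccadeEvent], cfg: DetectionConfig
) -> list[SaccadeEvent]:
    """Drop small opposite-sign overshoot events trailing a large step."""
    keep: list[SaccadeEvent] = []
    for e in events:
        if (
            keep
            and e.direction != keep[-1].direction
            and e.time - keep[-1].time <= cfg.echo_window
            and e.magnitude <= cfg.echo_fraction * keep[-1].magnitude
        ):
            continue
        keep.append(e)
    return keep


def _merge_refractory(
    events: list[SaccadeEvent], refractory: float
) -> list[SaccadeEvent]:
    """Merge same-sign events closer than the refractory gap."""
    merged: list[SaccadeEvent] = []
    for e in events:
        if (
            merged
            and e.direction == merged[-1].direction
            and e.time - merged[-1].time < refractory
        ):
            prev = merged[-1]
            bigger = e if e.magnitude > prev.magnitude else prev
            merged[-1] = SaccadeEvent(
                time=bigger.time,
                direction=e.direction,
                magnitude=abs(e.level_after - prev.level_before),
                position_estimate=e.position_estimate,
                channel=e.channel,
                level_before=prev.level_before,
                level_after=e.level_after,
            )
        else:
            merged.append(e)
    return merged


def _reject_blinks(
    events: list[SaccadeEvent], cfg: DetectionConfig
) -> list[SaccadeEvent]:
    """Drop opposite-sign pairs that return to baseline within the window.

    A blink shows as an up flank followed by a down flank of comparable
    size with essentially no net gaze displacement; a genuine pair of
    opposite saccades lands at a new level.
    """
    keep = [True] * len(events)
    for k in range(len(events) - 1):
        if not keep[k]:
            continue
        a, b = events[k], events[k + 1]
        if b.time - a.time > cfg.blink_window:
            continue
        opposite = {a.direction, b.direction} in (
            {"left", "right"}, {"up", "down"},
        )
        if not opposite:
            continue
        net = abs(b.level_after - a.level_before)
        if net < cfg.blink_net_fraction * 0.5 * (a.magnitude + b.magnitude):
            keep[k] = keep[k + 1] = False
    return [e for e, k in zip(events, keep) if k]


# ---------------------------------------------------------------------------
# one-to-one stimulus/event matching (RSOT)


@dataclass
class RsotResult:
    """Match counts and success percentages of the tracking statistic.

    ``matches``/``references``/``success`` are stage-by-direction tables;
    ``direction_accuracy`` averages each direction over the stages;
    ``overall_average`` is the plain mean of the four direction accuracies
    and ``weighted`` their 16/9-weighted combination.  Percentages are
    stored unrounded; :meth:`report` applies the two-decimal table
    convention.
    """

    matches: pd.DataFrame
    references: pd.DataFrame
    success: pd.DataFrame | None = None
    direction_accuracy: pd.Series | None = None
    overall_average: float | None = None
    weighted: float | None = None

    def report(self) -> dict:
        if self.success is None:
            raise ValueError("success rates not computed; call success_rates() first")
        return {
            "matches": self.matches.to_dict(),
            "references": self.references.to_dict(),
            "success": self.success.map(round2).to_dict(),
            "direction_accuracy": {
                d: round2(v) for d, v in self.direction_accuracy.items()
            },
            "overall_average": round2(self.overall_average),
            "weighted": round2(self.weighted),
        }


def _max_matching_pairs(compat: np.ndarray) -> list[tuple[int, int]]:
    """Maximum one-to-one matching of a boolean stimulus x event matrix."""
    if compat.size == 0 or not compat.any():
        return []
    m = maximum_bipartite_matching(
        csr_matrix(compat.astype(np.int8)), perm_type="column"
    )
    return [(i, int(j)) for i, j in enumerate(m) if j >= 0]


def rsot_match(
    events: Sequence[SaccadeEvent],
    schedule: StimulusSchedule,
    time_tol: float = 0.5,
    pos_tol: float | None = 0.15,
) -> RsotResult:
    """Match detected events one-to-one against same-direction stimuli.

    An event is compatible with a stimulus of the same direction when
    their times differ by at most ``time_tol`` seconds and (if ``pos_tol``
    is not None) the event's landing-position estimate lies within
    ``pos_tol`` normalized units of the stimulus coordinate.  Each
    stimulus and each event is used at most once; the tally is the size of
    a maximum bipartite matching, computed exactly.
    """
    if time_tol < 0 or (pos_tol is not None and pos_tol < 0):
        raise ValueError("tolerances must be nonnegative")
    refs = direction_counts(schedule)
    matches = refs.copy() * 0
    for d in DIRECTIONS:
        stim = [e for e in schedule.events if e.direction == d]
        evs = sorted(
            (e for e in events if e.direction == d), key=lambda e: e.time
        )
        if not stim or not evs:
            continue
        s_t = np.array([s.onset for s in stim])
        s_p = np.array(
            [s.x if d in HORIZONTAL_DIRECTIONS else s.y for s in stim]
        )
        e_t = np.array([e.time for e in evs])
        e_p = np.array([e.position_estimate for e in evs])
        compat = np.abs(e_t[None, :] - s_t[:, None]) <= time_tol
        if pos_tol is not None:
            compat &= np.abs(e_p[None, :] - s_p[:, None]) <= pos_tol
        for i, _ in _max_matching_pairs(compat):
            matches.loc[stim[i].stage, d] += 1
    return RsotResult(matches=matches, references=refs)


def success_rates(result: RsotResult) -> RsotResult:
    """Fill success percentages and the weighted overall score."""
    if (result.references <= 0).any().any():
        raise ValueError("every (stage, direction) cell needs a positive reference count")
    success = 100.0 * result.matches / result.references
    direction_accuracy = success.mean(axis=0)
    overall = float(direction_accuracy.mean())
    weighted = weighted_success(
        direction_accuracy["left"], direction_accuracy["right"],
        direction_accuracy["up"], direction_accuracy["down"],
    )
    return RsotResult(
        matches=result.matches, references=result.references,
        success=success, direction_accuracy=direction_accuracy,
        overall_average=overall, weighted=weighted,
    )


def weighted_success(left: float, right: float, up: float, down: float) -> float:
    """Aspect-weighted overall tracking success percentage.

    Horizontal accuracies (detected on the wide screen axis) carry weight
    16, vertical ones weight 9, over a total of 25::

        (((left + right) / 2) * 16 + ((up + down) / 2) * 9) / 25
    """
    for name, v in (("left", left), ("right", right), ("up", up), ("down", down)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} accuracy must be in [0, 100], got {v}")
    return (((left + right) / 2.0) * 16.0 + ((up + down) / 2.0) * 9.0) / 25.0


# ---------------------------------------------------------------------------
# complexity / statistical descriptors


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a time series.

    For each delay k = 1..kmax the mean normalized curve length L(k) over
    the k interleaved subsequences is computed with the usual
    (N-1) / (floor((N-m)/k) * k^2) normalization; the dimension is the
    negated slope of the least-squares fit of ln L(k) on ln k.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if n < 2 * kmax + 2:
        raise ValueError(f"need at least 2*kmax+2 samples (N={n}, kmax={kmax})")
    log_k = np.empty(kmax)
    log_L = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            n_m = len(sub) - 1
            if n_m < 1:
                continue
            lengths.append(
                np.sum(np.abs(np.diff(sub))) * (n - 1) / (n_m * k * k)
            )
        log_k[k - 1] = np.log(k)
        log_L[k - 1] = np.log(np.mean(lengths))
    slope = np.polyfit(log_k, log_L, 1)[0]
    return float(-slope)


@dataclass(frozen=True)
class HjorthTriple:
    """Hjorth activity, mobility and complexity of one signal."""

    activity: float
    mobility: float
    complexity: float


def hjorth_params(x: np.ndarray) -> HjorthTriple:
    """Hjorth descriptors: variance, and first/second difference ratios.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx) / mobility(x).  Constant signals have no
    defined mobility and are rejected.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    var0 = float(np.var(x))
    if var0 == 0.0:
        raise ValueError("constant signal has zero variance")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var1 = float(np.var(d1))
    var2 = float(np.var(d2))
    mobility = math.sqrt(var1 / var0)
    mobility_d = math.sqrt(var2 / var1) if var1 > 0 else 0.0
    complexity = mobility_d / mobility if mobility > 0 else 0.0
    return HjorthTriple(activity=var0, mobility=mobility, complexity=complexity)


def cgd_rate(responses: Iterable[bool | int]) -> float:
    """Percentage of positive colour-rule reports, to two decimals."""
    responses = list(responses)
    if not responses:
        raise ValueError("need at least one response")
    return round2(100.0 * sum(bool(r) for r in responses) / len(responses))


# ---------------------------------------------------------------------------
# per-subject feature vector


@dataclass(frozen=True)
class FeatureVector:
    """One classifier input row: RSOT, CGD, and per-stage HFD + Hjorth."""

    rsot_weighted: float
    cgd: int
    hfd: Mapping[tuple[int, str], float]
    activity: Mapping[tuple[int, str], float]
    mobility: Mapping[tuple[int, str], float]
    complexity: Mapping[tuple[int, str], float]
    subject_id: str = ""
    rsot_detail: RsotResult | None = field(default=None, compare=False)

    _STAGES = (1, 2, 3)

    def to_series(self) -> pd.Series:
        data: dict[str, float] = {
            "rsot_weighted": self.rsot_weighted,
            "cgd": float(self.cgd),
        }
        for s in self._STAGES:
            for c in CHANNELS:
                lc = c.lower()
                data[f"hfd_s{s}_{lc}"] = self.hfd[(s, c)]
                data[f"activity_s{s}_{lc}"] = self.activity[(s, c)]
                data[f"mobility_s{s}_{lc}"] = self.mobility[(s, c)]
                data[f"complexity_s{s}_{lc}"] = self.complexity[(s, c)]
        return pd.Series(data, name=self.subject_id or None)

    def channel_means(self) -> pd.DataFrame:
        """Per-stage values averaged over the two channels (summary layout)."""
        rows = {}
        for s in self._STAGES:
            rows[s] = {
                "hfd": np.mean([self.hfd[(s, c)] for c in CHANNELS]),
                "activity": np.mean([self.activity[(s, c)] for c in CHANNELS]),
                "mobility": np.mean([self.mobility[(s, c)] for c in CHANNELS]),
                "complexity": np.mean([self.complexity[(s, c)] for c in CHANNELS]),
            }
        df = pd.DataFrame(rows).T
        df.index.name = "stage"
        return df


def assemble_features(
    rsot: RsotResult,
    cgd: int,
    hfd: Mapping[tuple[int, str], float],
    hjorth: Mapping[tuple[int, str], HjorthTriple],
    subject_id: str = "",
) -> FeatureVector:
    """Combine the computed pieces into one flat, complete feature row."""
    if rsot.weighted is None:
        raise ValueError("rsot must have success rates filled (run success_rates)")
    expected = {(s, c) for s in (1, 2, 3) for c in CHANNELS}
    for name, mapping in (("hfd", hfd), ("hjorth", hjorth)):
        missing = expected - set(mapping)
        if missing:
            raise ValueError(f"{name} missing cells: {sorted(missing)}")
    return FeatureVector(
        rsot_weighted=float(rsot.weighted),
        cgd=int(bool(cgd)),
        hfd={k: float(hfd[k]) for k in expected},
        activity={k: hjorth[k].activity for k in expected},
        mobility={k: hjorth[k].mobility for k in expected},
        complexity={k: hjorth[k].complexity for k in expected},
        subject_id=subject_id,
        rsot_detail=rsot,
    )


# ---------------------------------------------------------------------------
# end-to-end extraction


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the recording -> feature-vector pipeline.

    The matcher runs on time and direction by default (``pos_tol=None``):
    landing-position estimates from a min-max-normalized trace are offset
    by baseline drift and blink artifacts, so a finite position tolerance
    is opt-in.
    """

    target_rate: float = 20.0
    ssa: SsaConfig = field(default_factory=SsaConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    time_tol: float = 0.5
    pos_tol: float | None = None
    kmax: int = 8
    ssa_per_section: bool = False


def extract_features(
    rec: EogRecording,
    schedule: StimulusSchedule,
    cgd: int = 0,
    cfg: PipelineConfig | None = None,
) -> FeatureVector:
    """Compute the full feature vector of one recording."""
    cfg = cfg or PipelineConfig()
    clean, _segments = preprocess_recording(
        rec, schedule, target_rate=cfg.target_rate, ssa=cfg.ssa,
        per_section=cfg.ssa_per_section,
    )
    events: list[SaccadeEvent] = []
    for ch in CHANNELS:
        events.extend(
            detect_events(clean.channel(ch), ch, rate=clean.rate, cfg=cfg.detection)
        )
    events.sort(key=lambda e: e.time)
    rsot = success_rates(
        rsot_match(events, schedule, time_tol=cfg.time_tol, pos_tol=cfg.pos_tol)
    )
    hfd: dict[tuple[int, str], float] = {}
    hjorth: dict[tuple[int, str], HjorthTriple] = {}
    for stage in range(1, schedule.n_stages + 1):
        t0, t1 = schedule.stage_bounds(stage)
        i0, i1 = int(t0 * clean.rate), int(t1 * clean.rate)
        for ch in CHANNELS:
            seg = clean.channel(ch)[i0:i1]
            hfd[(stage, ch)] = higuchi_fd(seg, kmax=cfg.kmax)
            hjorth[(stage, ch)] = hjorth_params(seg)
    return assemble_features(rsot, cgd, hfd, hjorth, subject_id=rec.subject_id)


def features_table(
    recordings: Sequence[EogRecording],
    cgd_responses: Sequence[int],
    schedule: StimulusSchedule,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Feature rows for a cohort, indexed by subject id."""
    if len(recordings) != len(cgd_responses):
        raise ValueError("recordings and cgd_responses must align")
    rows = [
        extract_features(rec, schedule, cgd=cgd, cfg=cfg).to_series()
        for rec, cgd in zip(recordings, cgd_responses)
    ]
    table = pd.DataFrame(rows)
    table.index = [r.subject_id for r in recordings]
    table.index.name = "subject_id"
    return table
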