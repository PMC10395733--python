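"""Stimulus model for the three-stage visual tracking test.

The test presents a small visual target that jumps between vertices of a
square- or z-shaped trajectory on a 16:9 screen.  Stage 1 (55 s) shows the
moving target alone; stage 2 (60 s) adds sudden visual distractors (animal
pictures); stage 3 (60 s) adds auditory distractors on top.  Over the whole
run the stimulus/background colours cycle through ten periods in which the
background colour of one period equals the stimulus colour of the next —
the hidden rule probed by the colour-game question.

This module encodes the test as plain data (:class:`StimulusSchedule`) and
renders the piecewise-constant reference calibration signals an ideal
tracker would produce, which downstream modules compare against recorded
eye movements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTIONS",
    "HORIZONTAL_DIRECTIONS",
    "VERTICAL_DIRECTIONS",
    "DEFAULT_COLOURS",
    "ConfigurationError",
    "StimulusEvent",
    "StimulusSchedule",
    "ReferenceSignal",
    "TestConfig",
    "build_schedule",
    "render_reference",
    "direction_counts",
]

DIRECTIONS = ("left", "right", "up", "down")
HORIZONTAL_DIRECTIONS = ("left", "right")
VERTICAL_DIRECTIONS = ("up", "down")

#: Ten colour periods; background of period i is the stimulus colour of i+1.
DEFAULT_COLOURS = (
    "red", "green", "blue", "yellow", "purple",
    "orange", "cyan", "magenta", "pink", "white",
)

#: Trajectory vertex levels per template: (x_levels, y_levels) in normalized
#: screen coordinates (origin bottom-left, 16:9 aspect recorded as metadata).
TEMPLATES = {
    "square": ((0.2, 0.8), (0.25, 0.75)),
    "z": ((0.15, 0.85), (0.3, 0.7)),
}


class ConfigurationError(ValueError):
    """Raised when a test configuration violates the schedule contract."""


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus jump: where the target lands and when."""

    onset: float                 # seconds from test start
    x: float                     # normalized horizontal position in [0, 1]
    y: float                     # normalized vertical position in [0, 1]
    direction: str               # movement from the previous position
    stage: int                   # 1..3
    colour: str
    distractor_visual: bool = False
    distractor_auditory: bool = False


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus events plus stage and colour-period bookkeeping."""

    events: tuple[StimulusEvent, ...]
    stage_durations: tuple[float, ...] = (55.0, 60.0, 60.0)
    colour_periods: tuple[tuple[str, str], ...] = ()
    aspect: tuple[int, int] = (16, 9)
    start_position: tuple[float, float] = (0.2, 0.25)

    @property
    def total_duration(self) -> float:
        return float(sum(self.stage_durations))

    @property
    def n_stages(self) -> int:
        return len(self.stage_durations)

    def stage_bounds(self, stage: int) -> tuple[float, float]:
        """Half-open time span ``[t0, t1)`` of a 1-based stage."""
        if not 1 <= stage <= self.n_stages:
            raise ValueError(f"stage must be 1..{self.n_stages}, got {stage}")
        t0 = float(sum(self.stage_durations[: stage - 1]))
        return t0, t0 + float(self.stage_durations[stage - 1])

    def events_in_stage(self, stage: int) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.stage == stage)

    def to_dict(self) -> dict:
        return {
            "stage_durations_s": list(self.stage_durations),
            "aspect": list(self.aspect),
            "start_position": list(self.start_position),
            "colour_periods": [list(p) for p in self.colour_periods],
            "events": [
                {
                    "onset_s": e.onset,
                    "x": e.x,
                    "y": e.y,
                    "direction": e.direction,
                    "stage": e.stage,
                    "colour": e.colour,
                    "distractor_visual": e.distractor_visual,
                    "distractor_auditory": e.distractor_auditory,
                }
                for e in self.events
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        events = tuple(
            StimulusEvent(
                onset=e["onset_s"], x=e["x"], y=e["y"], direction=e["direction"],
                stage=e["stage"], colour=e["colour"],
                distractor_visual=e["distractor_visual"],
                distractor_auditory=e["distractor_auditory"],
            )
            for e in d["events"]
        )
        return cls(
            events=events,
            stage_durations=tuple(d["stage_durations_s"]),
            colour_periods=tuple(tuple(p) for p in d["colour_periods"]),
            aspect=tuple(d.get("aspect", (16, 9))),
            start_position=tuple(d.get("start_position", (0.2, 0.25))),
        )

    @classmethod
    def from_json(cls, path) -> "StimulusSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ReferenceSignal:
    """Piecewise-constant ideal-tracker trace, one channel per screen axis."""

    rate: float
    horizontal: np.ndarray
    vertical: np.ndarray

    def __post_init__(self):
        if len(self.horizontal) != len(self.vertical):
            raise ValueError("reference channels must have equal length")


@dataclass(frozen=True)
class TestConfig:
    """Configuration of the tracking test.

    ``direction_counts`` gives the number of stimulus jumps per direction in
    every stage; left/right and up/down counts must balance so the target
    can alternate between the two vertex levels of each axis.
    """

    stage_durations: tuple[float, ...] = (55.0, 60.0, 60.0)
    direction_counts: Mapping[str, int] | Sequence[Mapping[str, int]] = field(
        default_factory=lambda: {"left": 40, "right": 40, "up": 30, "down": 30}
    )
    template: str = "square"
    colours: Sequence[str] = DEFAULT_COLOURS
    onset_jitter: float = 0.1          # fraction of the nominal inter-stimulus gap
    distractor_prob: float = 0.2       # chance a stage-2/3 event coincides with a distractor
    seed: int = 0

    def counts_for_stage(self, stage: int) -> dict[str, int]:
        c = self.direction_counts
        if isinstance(c, Mapping):
            per = c
        else:
            per = c[stage - 1]
        return {d: int(per.get(d, 0)) for d in DIRECTIONS}


def _validate_config(cfg: TestConfig) -> None:
    if len(cfg.stage_durations) < 1 or any(d <= 0 for d in cfg.stage_durations):
        raise ConfigurationError("stage durations must be positive")
    if cfg.template not in TEMPLATES:
        raise ConfigurationError(f"unknown trajectory template {cfg.template!r}")
    if len(cfg.colours) != 10:
        raise ConfigurationError("colour list must have length 10")
    if not 0 <= cfg.onset_jitter < 0.5:
        raise ConfigurationError("onset_jitter must be in [0, 0.5)")
    total = 0
    for stage in range(1, len(cfg.stage_durations) + 1):
        counts = cfg.counts_for_stage(stage)
        if any(v < 0 for v in counts.values()):
            raise ConfigurationError("direction counts must be nonnegative")
        if counts["left"] != counts["right"] or counts["up"] != counts["down"]:
            raise ConfigurationError(
                "left/right and up/down counts must balance within each stage"
            )
        total += sum(counts.values())
    if total == 0:
        raise ConfigurationError("schedule must contain at least one stimulus")


def build_schedule(cfg: TestConfig | None = None) -> StimulusSchedule:
    """Lay out the stimulus events of the three-stage test.

    Events sit on the vertices of the configured trajectory template and
    alternate along each axis, so direction labels are consistent with the
    sign of the displacement by construction.  Onsets are uniformly spaced
    within each stage with a small seeded jitter; the layout is fully
    deterministic for a fixed configuration.
    """
    cfg = cfg or TestConfig()
    _validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    x_levels, y_levels = TEMPLATES[cfg.template]

    colour_periods = tuple(
        (cfg.colours[i], cfg.colours[(i + 1) % 10]) for i in range(10)
    )
    total_duration = float(sum(cfg.stage_durations))

    # Alternation state per axis: index of the *current* vertex level.  The
    # target starts at the low vertex of both axes, so the first move on each
    # axis is rightward / upward.
    x_idx, y_idx = 0, 0
    x, y = x_levels[0], y_levels[0]

    events: list[StimulusEvent] = []
    t0 = 0.0
    for stage, dur in enumerate(cfg.stage_durations, start=1):
        counts = cfg.counts_for_stage(stage)
        n_h = counts["left"] + counts["right"]
        n_v = counts["up"] + counts["down"]
        n = n_h + n_v
        if n == 0:
            t0 += dur
            continue
        axes = np.array(["H"] * n_h + ["V"] * n_v)
        rng.shuffle(axes)
        gap = dur / n
        jitter = rng.uniform(-cfg.onset_jitter, cfg.onset_jitter, size=n)
        onsets = t0 + (np.arange(n) + 0.5 + jitter) * gap
        for onset, axis in zip(onsets, axes):
            if axis == "H":
                x_idx = 1 - x_idx
                new_x = x_levels[x_idx]
                direction = "right" if new_x > x else "left"
                x = new_x
            else:
                y_idx = 1 - y_idx
                new_y = y_levels[y_idx]
                direction = "up" if new_y > y else "down"
                y = new_y
            period = min(9, int(10 * (onset - t0) / dur))
            vis = bool(stage >= 2 and rng.random() < cfg.distractor_prob)
            aud = bool(stage >= 3 and rng.random() < cfg.distractor_prob)
            events.append(
                StimulusEvent(
                    onset=float(onset), x=float(x), y=float(y),
                    direction=direction, stage=stage,
                    colour=cfg.colours[period],
                    distractor_visual=vis, distractor_auditory=aud,
                )
            )
        t0 += dur

    onset_arr = np.array([e.onset for e in events])
    assert np.all(np.diff(onset_arr) > 0), "onsets must be strictly increasing"
    assert onset_arr[-1] < total_duration
    return StimulusSchedule(
        events=tuple(events),
        stage_durations=tuple(float(d) for d in cfg.stage_durations),
        colour_periods=colour_periods,
        start_position=(x_levels[0], y_levels[0]),
    )


def render_reference(schedule: StimulusSchedule, rate: float) -> ReferenceSignal:
    """Render the ideal-tracker calibration signals at a given rate.

    Both channels are piecewise constant, stepping to the new normalized
    stimulus coordinate at each event onset (the sample at
    ``floor(onset * rate)`` already carries the new value).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not schedule.events:
        raise ValueError("cannot render a reference for an empty schedule")
    n = int(schedule.total_duration * rate)
    onset_idx = np.array([int(e.onset * rate) for e in schedule.events])
    xs = np.array([e.x for e in schedule.events])
    ys = np.array([e.y for e in schedule.events])
    j = np.searchsorted(onset_idx, np.arange(n), side="right") - 1
    x0, y0 = schedule.start_position
    horizontal = np.where(j >= 0, xs[np.clip(j, 0, None)], x0)
    vertical = np.where(j >= 0, ys[np.clip(j, 0, None)], y0)
    return ReferenceSignal(rate=float(rate), horizontal=horizontal, vertical=vertical)


def direction_counts(schedule: StimulusSchedule) -> pd.DataFrame:
    """Stage-by-direction stimulus counts (the denominators of success rates)."""
    stages = range(1, schedule.n_stages + 1)
    table = pd.DataFrame(0, index=list(stages), columns=list(DIRECTIONS), dtype=int)
    table.index.name = "stage"
    for e in schedule.events:
        table.loc[e.stage, e.direction] += 1
    return table
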