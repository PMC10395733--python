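"""Signal conditioning: downsampling, normalization, SSA denoising, and
direction segmentation.

The analysis chain reduces a 500 Hz two-channel recording to clean,
normalized 20 Hz traces: anti-aliased decimation, per-channel min-max
scaling to [0, 1], singular-spectrum-analysis (SSA) denoising, and a split
of each stage's timeline into the four movement-direction sections (3
stages x 4 directions = 12 sections) used to score tracking per test part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sps
from scipy.linalg import hankel

from .simulate import EogRecording
from .stimulus import DIRECTIONS, HORIZONTAL_DIRECTIONS, StimulusSchedule

__all__ = [
    "SsaConfig",
    "Section",
    "DirectionalSegments",
    "downsample",
    "normalize_amplitude",
    "ssa_denoise",
    "segment_directions",
    "preprocess_recording",
]


def downsample(rec: EogRecording, target_rate: float = 20.0) -> EogRecording:
    """Anti-alias low-pass then decimate by an integer factor.

    The filter is a zero-phase 8th-order Butterworth with cutoff at 0.8x
    the target Nyquist (8 Hz for 20 Hz output), so step timing is preserved
    for downstream event matching.  Non-integer rate ratios are rejected:
    resampling dialects are deliberately out of scope.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    factor = rec.rate / target_rate
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ValueError(
            f"rate {rec.rate} is not an integer multiple of target {target_rate}"
        )
    if q == 1:
        return replace_channels(rec, rec.horizontal.copy(), rec.vertical.copy(), rec.rate)
    cutoff = 0.4 * target_rate          # 0.8 x (target_rate / 2)
    sos = sps.butter(8, cutoff, fs=rec.rate, output="sos")
    out = []
    for x in (rec.horizontal, rec.vertical):
        y = sps.sosfiltfilt(sos, x)
        out.append(y[::q].copy())
    return replace_channels(rec, out[0], out[1], target_rate)


def replace_channels(
    rec: EogRecording, h: np.ndarray, v: np.ndarray, rate: float
) -> EogRecording:
    return EogRecording(
        rate=float(rate), horizontal=h, vertical=v,
        subject_id=rec.subject_id, group=rec.group, truth=rec.truth,
    )


def _normalize(x: np.ndarray) -> np.ndarray:
    if len(x) == 0:
        raise ValueError("cannot normalize an empty channel")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("constant channel normalized to all zeros", stacklevel=3)
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def normalize_amplitude(rec: EogRecording) -> EogRecording:
    """Min-max scale each channel to [0, 1] (constant channels map to 0)."""
    return replace_channels(
        rec, _normalize(rec.horizontal), _normalize(rec.vertical), rec.rate
    )


@dataclass(frozen=True)
class SsaConfig:
    """SSA window length (samples) and how many components to keep.

    If ``components`` is None the reconstruction keeps the smallest leading
    set of singular components whose squared singular values capture at
    least ``energy`` of the total.
    """

    window: int = 20
    components: int | None = None
    energy: float = 0.95

    def n_components(self, s: np.ndarray) -> int:
        if self.components is not None:
            if not 1 <= self.components <= len(s):
                raise ValueError("components must be in 1..window")
            return self.components
        power = s**2
        cum = np.cumsum(power) / power.sum()
        return int(np.searchsorted(cum, self.energy) + 1)


def ssa_denoise(x: np.ndarray, cfg: SsaConfig | None = None) -> np.ndarray:
    """Singular spectrum analysis reconstruction from leading components.

    Full SSA cycle: embed the series in its L x K trajectory (Hankel)
    matrix, take the SVD, keep the leading component group, and map back to
    a series by diagonal (anti-diagonal) averaging.  With all L components
    retained the reconstruction reproduces the input exactly (up to
    floating point), which is the completeness identity used in tests.
    """
    cfg = cfg or SsaConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = cfg.window
    if not 2 <= L <= n // 2:
        raise ValueError(f"SSA window must satisfy 2 <= L <= N/2 (L={L}, N={n})")
    # centre the series so the energy criterion ranks structure, not the DC
    # offset (whose rank-1 component would otherwise absorb ~all energy)
    mean = float(x.mean())
    x = x - mean
    K = n - L + 1
    X = hankel(x[:L], x[L - 1 :])            # L x K trajectory matrix
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = cfg.n_components(s)
    Xr = (U[:, :r] * s[:r]) @ Vt[:r]
    recon = np.zeros(n)
    counts = np.zeros(n)
    for i in range(L):
        recon[i : i + K] += Xr[i]
        counts[i : i + K] += 1.0
    return recon / counts + mean


@dataclass(frozen=True)
class Section:
    """Samples of one (stage, direction) section of a recording."""

    stage: int
    direction: str
    channel: str                       # "H" for left/right, "V" for up/down
    indices: np.ndarray                # sample indices into the recording
    spans: tuple[tuple[float, float], ...]  # time intervals owned, seconds

    @property
    def duration(self) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.spans))


@dataclass(frozen=True)
class DirectionalSegments:
    """The 12 (stage x direction) sections of a preprocessed recording."""

    sections: Mapping[tuple[int, str], Section]
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "sections", dict(self.sections))

    def section(self, stage: int, direction: str) -> Section:
        return self.sections[(stage, direction)]

    def samples(self, rec: EogRecording, stage: int, direction: str) -> np.ndarray:
        sec = self.section(stage, direction)
        return rec.channel(sec.channel)[sec.indices]


def segment_directions(
    rec: EogRecording, schedule: StimulusSchedule
) -> DirectionalSegments:
    """Partition each stage's timeline into the four direction sections.

    A section owns the half-open interval from each of its events' onsets
    to the next event onset (the last event runs to the stage end, and the
    pre-first-event span belongs to the first event), so the four sections
    of a stage tile the stage exactly once.  Horizontal directions read
    channel 1 (``H``), vertical directions channel 2 (``V``).  Directions
    with no events in a stage yield empty, warned-about sections.
    """
    if rec.duration < schedule.total_duration - 0.5 / rec.rate:
        raise ValueError(
            f"recording ({rec.duration:.2f} s) shorter than schedule "
            f"({schedule.total_duration:.2f} s)"
        )
    rate = rec.rate
    sections: dict[tuple[int, str], Section] = {}
    for stage in range(1, schedule.n_stages + 1):
        t0, t1 = schedule.stage_bounds(stage)
        events = schedule.events_in_stage(stage)
        boundaries = [t0] + [e.onset for e in events[1:]] + [t1]
        owners: dict[str, list[tuple[float, float]]] = {d: [] for d in DIRECTIONS}
        for e, lo, hi in zip(events, boundaries[:-1], boundaries[1:]):
            owners[e.direction].append((lo, hi))
        for d in DIRECTIONS:
            spans = owners[d]
            idx_parts = [
                np.arange(int(np.ceil(lo * rate)), int(np.ceil(hi * rate)))
                for lo, hi in spans
            ]
            indices = (
                np.concatenate(idx_parts) if idx_parts else np.array([], dtype=int)
            )
            indices = indices[indices < rec.n_samples]
            if len(indices) == 0:
                warnings.warn(
                    f"stage {stage} has no {d!r} events; section is empty",
                    stacklevel=2,
                )
            sections[(stage, d)] = Section(
                stage=stage, direction=d,
                channel="H" if d in HORIZONTAL_DIRECTIONS else "V",
                indices=indices, spans=tuple(spans),
            )
    return DirectionalSegments(sections=sections, rate=rate)


def preprocess_recording(
    rec: EogRecording,
    schedule: StimulusSchedule,
    target_rate: float = 20.0,
    ssa: SsaConfig | None = None,
    per_section: bool = False,
) -> tuple[EogRecording, DirectionalSegments]:
    """Run the full conditioning chain on one recording.

    Order: downsample -> normalize -> SSA denoise -> segment.  By default
    SSA runs on each whole channel; ``per_section=True`` instead denoises
    each direction section's (concatenated) samples separately and
    scatters them back, which can leave seam discontinuities between
    non-adjacent intervals and is therefore not the default.
    """
    ssa = ssa or SsaConfig()
    ds = downsample(rec, target_rate)
    norm = normalize_amplitude(ds)
    if per_section:
        segments = segment_directions(norm, schedule)
        h = norm.horizontal.copy()
        v = norm.vertical.copy()
        for (stage, d), sec in segments.sections.items():
            if len(sec.indices) < 2 * ssa.window:
                continue
            target = h if sec.channel == "H" else v
            target[sec.indices] = ssa_denoise(target[sec.indices], ssa)
        clean = replace_channels(norm, h, v, norm.rate)
    else:
        clean = replace_channels(
            norm,
            ssa_denoise(norm.horizontal, ssa),
            ssa_denoise(norm.vertical, ssa),
            norm.rate,
        )
    segments = segment_directions(clean, schedule)
    return clean, segments
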