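"""Beat splitting, quality filtering and 10-segment vPPG normalization.

A recording is cut into heartbeats at consecutive W points (the vPPG
maximum, i.e. the steepest systolic upstroke — the most reliably detected
fiducial).  Each W-to-W beat is amplitude-normalized to [0, 1], converted
to PPG velocity (forward difference ×100, so units are percent of beat
amplitude per sample at 62.5 Hz), and reduced to 10 segment values: the
mean velocity over 10 near-equal contiguous phase blocks of the cardiac
cycle.  A ≥30 s measurement then becomes one *dataset summary*: the
per-segment mean ± SD over its accepted beats (typically 31–48 of them).

A measurement in which more than 10% of beats are abnormal (overlapping a
noise interval, missing fiducials, or outside the plausible heart-rate
range) is flagged for re-measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signal_io import PPGRecord

#: Number of phase segments per heartbeat.
N_SEGMENTS = 10
#: Fraction of abnormal beats above which re-measurement is requested.
ABNORMAL_LIMIT = 0.10
#: Minimum accepted beats for an analysis-grade summary.
MIN_BEATS = 30
#: Physiological W-to-W interval bounds in seconds (HR 30–150 bpm).
HR_INTERVAL = (0.4, 2.0)


class BeatError(ValueError):
    """Raised for degenerate beats or insufficient beat counts."""


@dataclass(frozen=True)
class Beat:
    """Fiducial indices of one heartbeat: onset O, upstroke max W, systolic
    peak S, first reflection-wave velocity peak Z (``None`` when absent)."""

    O: int | None
    W: int
    S: int | None
    Z: int | None
    abnormal: bool = False

    def ordered(self) -> bool:
        pts = [p for p in (self.O, self.W, self.S, self.Z) if p is not None]
        return all(a <= b for a, b in zip(pts, pts[1:]))


@dataclass
class FeaturePointSet:
    """Per-beat fiducials plus noise-region intervals for one record.

    ``noise_intervals`` are half-open ``[start, end)`` sample intervals.
    Beats are kept sorted by W.
    """

    beats: list[Beat] = field(default_factory=list)
    noise_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.beats = sorted(self.beats, key=lambda b: b.W)
        for b in self.beats:
            if not b.ordered():
                raise BeatError(f"fiducials out of order: {b}")

    @property
    def w_points(self) -> np.ndarray:
        return np.array([b.W for b in self.beats], dtype=int)


@dataclass(frozen=True)
class BeatSegmentValues:
    """The 10 segment values of one beat: mean vPPG (percent of beat
    amplitude per sample) over each phase decile of the cardiac cycle."""

    values: np.ndarray
    beat_duration: float

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_SEGMENTS,) or not np.all(np.isfinite(vals)):
            raise BeatError(f"expected {N_SEGMENTS} finite segment values")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-segment mean ± SD over the accepted beats of one measurement."""

    means: np.ndarray
    sds: np.ndarray
    n_beats: int
    remeasure_flag: bool = False
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self):
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if m.shape != (N_SEGMENTS,) or s.shape != (N_SEGMENTS,):
            raise BeatError(f"summaries carry exactly {N_SEGMENTS} segments")
        if np.any(s < 0):
            raise BeatError("segment SDs must be non-negative")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def analysis_grade(self) -> bool:
        return self.n_beats >= MIN_BEATS and not self.remeasure_flag

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject": self.subject_id,
                "session": self.session_id,
                "n_beats": int(self.n_beats),
                "remeasure": bool(self.remeasure_flag),
                "means": [float(x) for x in self.means],
                "sds": [float(x) for x in self.sds],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetSummary":
        d = json.loads(text)
        return cls(
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            n_beats=d["n_beats"],
            remeasure_flag=d.get("remeasure", False),
            subject_id=d.get("subject"),
            session_id=d.get("session"),
        )


# ---------------------------------------------------------------------------
# Beat extraction
# ---------------------------------------------------------------------------

def _overlaps(start: int, end: int, intervals) -> bool:
    return any(start < e and s < end for s, e in intervals)


def split_beats(
    record: PPGRecord, points: FeaturePointSet
) -> tuple[list[tuple[int, int]], int]:
    """Half-open W-to-W beat ranges, with exclusions.

    Returns ``(accepted_ranges, n_abnormal)`` where a beat is abnormal when
    its source fiducials are flagged, it overlaps a noise interval, or its
    duration falls outside the 0.4–2.0 s heart-rate window.
    """
    ws = points.w_points
    if len(ws) < 2:
        raise BeatError(f"need at least 2 W points to split beats, got {len(ws)}")
    lo = int(round(HR_INTERVAL[0] * record.rate))
    hi = int(round(HR_INTERVAL[1] * record.rate))
    accepted, n_abnormal = [], 0
    for beat, w_next in zip(points.beats[:-1], ws[1:]):
        start, end = int(beat.W), int(w_next)
        bad = (
            beat.abnormal
            or not (lo <= end - start <= hi)
            or _overlaps(start, end, points.noise_intervals)
        )
        if bad:
            n_abnormal += 1
        else:
            accepted.append((start, end))
    return accepted, n_abnormal


def quality_filter(all_beats: int, abnormal_beats: int) -> bool:
    """Re-measure flag: True iff abnormal beats *exceed* 10% of all beats.

    Exactly 10% does not trigger the flag.
    """
    if all_beats <= 0:
        raise BeatError("quality rule undefined for zero beats")
    if not 0 <= abnormal_beats <= all_beats:
        raise BeatError("abnormal count must lie in [0, all_beats]")
    return abnormal_beats / all_beats > ABNORMAL_LIMIT


def normalize_beat(samples: np.ndarray) -> np.ndarray:
    """Min-max amplitude normalization of one beat to [0, 1]."""
    x = np.asarray(samples, dtype=float)
    if len(x) < int(round(HR_INTERVAL[0] * 62.5)):
        raise BeatError(f"beat too short: {len(x)} samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise BeatError("zero amplitude: constant beat cannot be normalized")
    return (x - lo) / (hi - lo)


def beat_vppg(normalized: np.ndarray) -> np.ndarray:
    """Beat velocity: forward difference of the normalized beat, ×100.

    Units are percent of beat amplitude per sample; the telescoping
    identity ``sum(out) == 100*(x[-1] - x[0])`` is exact.
    """
    x = np.asarray(normalized, dtype=float)
    if len(x) < 2:
        raise BeatError("beat shorter than 2 samples has no velocity")
    return 100.0 * np.diff(x)


def segment_values(velocity: np.ndarray, beat_duration: float = 0.0) -> BeatSegmentValues:
    """Reduce a beat's velocity series to 10 contiguous block means.

    Block ``i`` covers indices ``[floor(i*L/10), floor((i+1)*L/10))``, so
    remainder samples accrue to later blocks and no interpolation is done.
    """
    v = np.asarray(velocity, dtype=float)
    L = len(v)
    if L < N_SEGMENTS:
        raise BeatError(f"velocity series of length {L} cannot fill {N_SEGMENTS} segments")
    edges = [(i * L) // N_SEGMENTS for i in range(N_SEGMENTS + 1)]
    vals = np.array([v[edges[i]: edges[i + 1]].mean() for i in range(N_SEGMENTS)])
    return BeatSegmentValues(vals, beat_duration)


def beat_to_segments(record: PPGRecord, start: int, end: int) -> BeatSegmentValues:
    """normalize → differentiate → segment, for one half-open beat range."""
    samples = record.samples[start:end]
    velocity = beat_vppg(normalize_beat(samples))
    return segment_values(velocity, (end - start) / record.rate)


def summarize_dataset(
    beats: list[BeatSegmentValues],
    remeasure_flag: bool = False,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> DatasetSummary:
    """Per-segment mean and sample SD (n−1) across a measurement's beats.

    Fewer than 30 beats still summarizes, but the result is not analysis
    grade: segment statistics stabilize only with repeated measurement.
    """
    if len(beats) < 2:
        raise BeatError(f"need at least 2 beats to summarize, got {len(beats)}")
    mat = np.stack([b.values for b in beats])
    return DatasetSummary(
        means=mat.mean(axis=0),
        sds=mat.std(axis=0, ddof=1),
        n_beats=len(beats),
        remeasure_flag=remeasure_flag,
        subject_id=subject_id,
        session_id=session_id,
    )


@dataclass(frozen=True)
class AnalysisReport:
    """End-to-end per-record result: the summary plus bookkeeping counts."""

    summary: DatasetSummary
    n_total_beats: int
    n_abnormal_beats: int
    n_accepted_beats: int


def analyze_record(record: PPGRecord, points: FeaturePointSet) -> AnalysisReport:
    """Full normalization of one record given its feature points."""
    ranges, n_abnormal = split_beats(record, points)
    n_total = len(points.beats) - 1
    flag = quality_filter(n_total, n_abnormal)
    segs = [beat_to_segments(record, s, e) for s, e in ranges]
    summary = summarize_dataset(
        segs, remeasure_flag=flag,
        subject_id=record.subject_id, session_id=record.session_id,
    )
    return AnalysisReport(summary, n_total, n_abnormal, len(ranges))
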