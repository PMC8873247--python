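"""Reading, resampling and differentiating single-channel PPG recordings.

The photoplethysmogram (PPG) is an arbitrary-unit optical blood-volume
signal.  Everything downstream works at a fixed rate of 62.5 samples/s —
the transmission rate of typical pulse-oximeter front ends — where the
analysis window of 1.2 s is exactly 75 samples and the 16 ms window
stride is exactly one sample.

Two derivative signals are defined by forward first differences:

* vPPG ("PPG velocity")      v[i] = ppg[i+1] - ppg[i]
* aPPG ("PPG acceleration")  a[i] = v[i+1] - v[i]

The forward difference makes the telescoping identity
``sum(v) == ppg[-1] - ppg[0]`` exact, which the beat-normalization stage
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

#: Working sampling rate (samples/s): 1.2 s window = 75 samples, 16 ms = 1 sample.
WORKING_RATE = 62.5
#: Analysis window length in samples at the working rate (1.2 s).
WINDOW_SAMPLES = 75
#: Window stride in samples at the working rate (16 ms).
WINDOW_STRIDE = 1
#: Minimum duration (s) of an analysis-grade measurement.
MIN_DURATION = 30.0


class RecordError(ValueError):
    """Raised for unreadable, malformed or too-short recordings."""


def _as_float_array(samples, what: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise RecordError(f"{what} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise RecordError(f"{what} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True)
class PPGRecord:
    """A raw PPG sample series with its sampling rate and provenance labels."""

    samples: np.ndarray
    rate: float
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples, "samples"))
        if not self.rate > 0:
            raise RecordError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.rate

    @property
    def needs_resampling(self) -> bool:
        """True when the record is not at the 62.5 Hz working rate."""
        return abs(self.rate - WORKING_RATE) > 1e-9

    @property
    def analysis_grade(self) -> bool:
        """True for records long enough (>= 30 s) for a dataset summary."""
        return self.duration >= MIN_DURATION


@dataclass(frozen=True)
class VelocitySignal:
    """vPPG: forward first difference of a PPG record (length n-1)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples, "vPPG samples"))


@dataclass(frozen=True)
class AccelerationSignal:
    """aPPG: forward first difference of vPPG (length n-2)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples, "aPPG samples"))


@dataclass(frozen=True)
class AnalysisWindow:
    """One 1.2 s (75-sample) sliding window of PPG plus aligned vPPG.

    vPPG slot ``i`` covers the sample interval ``[i, i+1]``; the final slot
    of each window has no forward difference inside the window and is
    zero-padded.
    """

    start_index: int
    ppg_segment: np.ndarray
    vppg_segment: np.ndarray

    def __post_init__(self):
        if len(self.ppg_segment) != WINDOW_SAMPLES or len(self.vppg_segment) != WINDOW_SAMPLES:
            raise ValueError("analysis windows are exactly 75 samples of PPG and vPPG")


# ---------------------------------------------------------------------------
# File I/O
#
# CSV dialect: one sample per line; an optional leading header line
# "rate=<value>" (a "# " comment prefix is tolerated).  WFDB support is a
# minimal reader for single-channel format-16 record/header pairs.
# ---------------------------------------------------------------------------

def load_record(
    path,
    format: str | None = None,
    rate: float | None = None,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> PPGRecord:
    """Load a PPG recording from a CSV sample series or a WFDB record.

    Parameters
    ----------
    path : path-like
        For CSV, the sample file; for WFDB, either the ``.hea`` header or
        the record name (path without extension).
    format : {"csv", "wfdb"}, optional
        Inferred from the extension when omitted (``.hea``/``.dat`` → wfdb).
    rate : float, optional
        Sampling rate, required for CSV files without a ``rate=`` header.

    No resampling is performed; check :attr:`PPGRecord.needs_resampling`.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") or (
            not path.suffix and path.with_suffix(".hea").exists()
        ) else "csv"
    if format == "csv":
        return _load_csv(path, rate, subject_id, session_id)
    if format == "wfdb":
        return _load_wfdb(path, subject_id, session_id)
    raise RecordError(f"unknown record format {format!r}")


def _load_csv(path: Path, rate, subject_id, session_id) -> PPGRecord:
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise RecordError(f"cannot read {path}: {exc}") from exc
    samples = []
    for row, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.lstrip("# ").startswith("rate="):
            rate = float(text.lstrip("# ").split("=", 1)[1])
            continue
        try:
            value = float(text)
        except ValueError as exc:
            raise RecordError(f"{path}: non-numeric sample at row {row}: {text!r}") from exc
        if not np.isfinite(value):
            raise RecordError(f"{path}: non-finite sample at row {row}: {text!r}")
        samples.append(value)
    if rate is None:
        raise RecordError(f"{path}: no sampling rate in header and none supplied")
    return PPGRecord(np.array(samples), float(rate), subject_id, session_id)


def save_record(record: PPGRecord, path) -> None:
    """Write the CSV dialect; integer-valued samples round-trip bit-identically."""
    path = Path(path)
    rate = record.rate
    rate_text = str(int(rate)) if rate == int(rate) else repr(rate)
    lines = [f"rate={rate_text}"]
    for x in record.samples:
        lines.append(str(int(x)) if x == int(x) else repr(float(x)))
    path.write_text("\n".join(lines) + "\n")


def _load_wfdb(path: Path, subject_id, session_id) -> PPGRecord:
    """Minimal single-channel WFDB reader (header + format-16 .dat)."""
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    try:
        lines = [
            ln for ln in header.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    except OSError as exc:
        raise RecordError(f"cannot read WFDB header {header}: {exc}") from exc
    head = lines[0].split()
    if len(head) < 3:
        raise RecordError(f"{header}: malformed WFDB record line")
    n_sig = int(head[1])
    if n_sig != 1:
        raise RecordError(f"{header}: only single-channel WFDB records are supported, got {n_sig}")
    fs = float(head[2].split("/")[0])
    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1].split("x")[0].split(":")[0].split("+")[0]
    if fmt != "16":
        raise RecordError(f"{header}: only WFDB format 16 is supported, got format {fmt}")
    gain, baseline = 200.0, 0
    if len(sig) >= 3:
        gain_field = sig[2].split("/")[0]
        if "(" in gain_field:
            gain_s, base_s = gain_field.split("(")
            gain = float(gain_s) if gain_s else 200.0
            baseline = int(base_s.rstrip(")"))
        else:
            gain = float(gain_field)
    if gain == 0:
        gain = 200.0
    raw = np.fromfile(header.parent / dat_name, dtype="<i2")
    samples = (raw.astype(float) - baseline) / gain
    return PPGRecord(samples, fs, subject_id, session_id)


# ---------------------------------------------------------------------------
# Resampling and derivatives
# ---------------------------------------------------------------------------

def resample(record: PPGRecord, target_rate: float = WORKING_RATE) -> PPGRecord:
    """Polyphase resampling to ``target_rate`` (anti-aliased on the way down).

    Duration is preserved to within one sample period; an identical record
    is returned when the rates already match.
    """
    if not target_rate > 0:
        raise RecordError(f"target rate must be positive, got {target_rate}")
    if abs(record.rate - target_rate) < 1e-9:
        return record
    ratio = Fraction(target_rate) / Fraction(record.rate)
    ratio = ratio.limit_denominator(10_000)
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator, padtype="line")
    return replace(record, samples=out, rate=float(target_rate))


def differentiate(signal: PPGRecord | VelocitySignal) -> VelocitySignal | AccelerationSignal:
    """Forward first difference: PPG → vPPG, vPPG → aPPG."""
    if len(signal.samples) < 2:
        raise RecordError("need at least 2 samples to differentiate")
    diff = np.diff(signal.samples)
    if isinstance(signal, VelocitySignal):
        return AccelerationSignal(diff, signal.rate)
    return VelocitySignal(diff, signal.rate)


def sliding_windows(record: PPGRecord) -> list[AnalysisWindow]:
    """All 75-sample analysis windows at stride 1 (count = n_samples - 74)."""
    ppg_mat, vppg_mat, starts = window_matrices(record)
    return [
        AnalysisWindow(int(s), ppg_mat[i], vppg_mat[i])
        for i, s in enumerate(starts)
    ]


def window_matrices(record: PPGRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window extraction: (PPG n×75, vPPG n×75, start indices).

    Row ``i`` matches ``sliding_windows(record)[i]`` exactly; used by the
    detector stage to encode a whole record in one pass.
    """
    if record.needs_resampling:
        raise RecordError(
            f"windowing requires the {WORKING_RATE} Hz working rate, got {record.rate}"
        )
    n = record.n_samples
    if n < WINDOW_SAMPLES:
        raise RecordError(
            f"record too short for one 1.2 s window: {n} < {WINDOW_SAMPLES} samples"
        )
    ppg = np.lib.stride_tricks.sliding_window_view(record.samples, WINDOW_SAMPLES).copy()
    v = np.diff(record.samples)
    vppg = np.zeros_like(ppg)
    vppg[:, :-1] = np.lib.stride_tricks.sliding_window_view(v, WINDOW_SAMPLES - 1)
    starts = np.arange(n - WINDOW_SAMPLES + 1)
    return ppg, vppg, starts
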