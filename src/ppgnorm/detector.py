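"""Fiducial-point and noise-region detection with six small networks.

Six identical feed-forward networks (two hidden layers of 124 units, 21
outputs) scan the record through 1.2 s windows shifted one sample (16 ms)
at a time.  All six receive the same 210-value encoding of a window —
75 min-max-scaled PPG samples, 75 scaled vPPG samples, and 60 binary
flags marking the locations of the highest and lowest peaks of PPG and
vPPG within the central 0.3 s — and each localizes one feature: the O,
S, W or Z fiducial, or the start or end of a noise region.

The 21 outputs are decoded as 20 position bins of 16 ms (one sample)
covering a 0.32 s region centered in the window, plus one "absent" class.
Because the window slides one sample at a time, every point of the record
is seen by ~20 overlapping windows; per-window decisions are then
majority-voted into absolute sample positions and assembled into beats
(:func:`reconcile`).

A deterministic rule-based detector (:func:`oracle_detect`) provides the
same output on artifact-free signals and doubles as the labeling oracle
in evaluations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.model_selection import train_test_split

from .beatnorm import Beat, FeaturePointSet, HR_INTERVAL
from .signal_io import AnalysisWindow, PPGRecord, WINDOW_SAMPLES, window_matrices

#: The six detector targets.
FEATURES = ("O", "S", "W", "Z", "noise_start", "noise_end")
#: First sample of the central decode region within a 75-sample window.
CENTRAL_START = 28
#: Decode region length: 20 bins of one sample (16 ms) each, ~0.3 s.
DECODE_BINS = 20
#: Class index meaning "feature not present in the central region".
ABSENT = DECODE_BINS
#: Peak-flag layout: 4 channels (PPG max/min, vPPG max/min) x 15 bins.
FLAG_CHANNELS = 4
FLAG_BINS = 15
#: Encoding length: 75 PPG + 75 vPPG + 60 peak flags.
ENCODING_LENGTH = 2 * WINDOW_SAMPLES + FLAG_CHANNELS * FLAG_BINS
#: Hidden layout of every detector network.
HIDDEN_LAYERS = (124, 124)


class DetectorError(ValueError):
    """Raised for malformed windows, untrained detectors or bad labels."""


# ---------------------------------------------------------------------------
# Window encoding
# ---------------------------------------------------------------------------

def _minmax_rows(mat: np.ndarray) -> np.ndarray:
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    span[flat] = 1.0
    out = (mat - lo) / span
    out[flat] = 0.5
    return out


def _peak_flags(mat: np.ndarray, maximize: bool) -> np.ndarray:
    """One-hot 15-bin location of the central-region extremum per row.

    Flat central segments produce all-zero flags.
    """
    central = mat[:, CENTRAL_START: CENTRAL_START + DECODE_BINS]
    idx = np.argmax(central, axis=1) if maximize else np.argmin(central, axis=1)
    flags = np.zeros((len(mat), FLAG_BINS))
    flat = central.max(axis=1) == central.min(axis=1)
    bins = (idx * FLAG_BINS) // DECODE_BINS
    flags[np.arange(len(mat)), bins] = 1.0
    flags[flat] = 0.0
    return flags


def encode_matrix(ppg_mat: np.ndarray, vppg_mat: np.ndarray) -> np.ndarray:
    """Batch window encoding: rows of 210 values in [0, 1]."""
    if ppg_mat.shape[1] != WINDOW_SAMPLES or vppg_mat.shape != ppg_mat.shape:
        raise DetectorError(f"windows must be {WINDOW_SAMPLES} samples of PPG and vPPG")
    return np.hstack(
        [
            _minmax_rows(ppg_mat),
            _minmax_rows(vppg_mat),
            _peak_flags(ppg_mat, True),
            _peak_flags(ppg_mat, False),
            _peak_flags(vppg_mat, True),
            _peak_flags(vppg_mat, False),
        ]
    )


def encode_window(window: AnalysisWindow) -> np.ndarray:
    """The 210-value detector input for one analysis window."""
    return encode_matrix(
        window.ppg_segment[None, :], window.vppg_segment[None, :]
    )[0]


def encode_record(record: PPGRecord) -> tuple[np.ndarray, np.ndarray]:
    """Encodings for every sliding window of a record: (X n×210, starts)."""
    ppg_mat, vppg_mat, starts = window_matrices(record)
    return encode_matrix(ppg_mat, vppg_mat), starts


def window_targets(starts: np.ndarray, positions: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-feature class labels for each window.

    A window whose central region contains a feature position gets that
    position's bin (0–19); otherwise the absent class (20).  ``positions``
    maps feature names to absolute sample indices (ground truth).
    """
    targets = {}
    for feature in FEATURES:
        pos = np.sort(np.asarray(positions.get(feature, ()), dtype=int))
        y = np.full(len(starts), ABSENT, dtype=int)
        if len(pos):
            lo = np.searchsorted(pos, starts + CENTRAL_START, side="left")
            inside = (lo < len(pos)) & (
                pos[np.minimum(lo, len(pos) - 1)] < starts + CENTRAL_START + DECODE_BINS
            )
            y[inside] = pos[lo[inside]] - starts[inside] - CENTRAL_START
        targets[feature] = y
    return targets


def make_training_set(
    labeled_records,
    max_windows: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Encode and label every window of ``(record, truth)`` pairs.

    ``truth`` may be a :class:`~ppgnorm.synthetic.GroundTruth` or any
    object with a ``feature_positions()`` method.  Windows are optionally
    subsampled (without replacement) to ``max_windows``.
    """
    xs, ys = [], {f: [] for f in FEATURES}
    for record, truth in labeled_records:
        X, starts = encode_record(record)
        targets = window_targets(starts, truth.feature_positions())
        xs.append(X)
        for f in FEATURES:
            ys[f].append(targets[f])
    X = np.vstack(xs)
    targets = {f: np.concatenate(ys[f]) for f in FEATURES}
    if max_windows is not None and len(X) > max_windows:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(X), size=max_windows, replace=False)
        keep.sort()
        X = X[keep]
        targets = {f: y[keep] for f, y in targets.items()}
    return X, targets


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Training knobs for the six networks (topology is fixed)."""

    seed: int = 0
    max_iter: int = 1000
    holdout_fraction: float = 0.25
    early_stopping: bool = True
    validation_fraction: float = 0.1
    n_iter_no_change: int = 80
    alpha: float = 1e-4
    learning_rate_init: float = 7e-4
    batch_size: int = 192


@dataclass(frozen=True)
class DetectionCandidate:
    """One detector's decision for one window."""

    feature: str
    bin_index: int | None
    confidence: float


@dataclass
class DetectorBank:
    """The six trained detectors plus their held-out bin accuracies."""

    detectors: dict[str, MLPClassifier]
    holdout_accuracy: dict[str, float]
    config: TrainingConfig
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = set(FEATURES) - set(self.detectors)
        if missing:
            raise DetectorError(f"detector bank is missing features: {sorted(missing)}")


def train_detectors(
    X: np.ndarray,
    targets: dict[str, np.ndarray],
    config: TrainingConfig = TrainingConfig(),
) -> DetectorBank:
    """Train the six feature detectors on encoded, labeled windows.

    All six share the same inputs; only the target labels differ.  Each
    network holds out ``holdout_fraction`` of the windows and reports its
    bin accuracy on them.  Training is deterministic under the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ENCODING_LENGTH:
        raise DetectorError(f"encoded windows must be n×{ENCODING_LENGTH}")
    if len(X) < 100:
        raise DetectorError(f"need at least 100 labeled windows, got {len(X)}")
    detectors, accuracy, notes = {}, {}, {}
    msgs = []
    for k, feature in enumerate(FEATURES):
        y = np.asarray(targets[feature], dtype=int)
        if len(y) != len(X):
            raise DetectorError(f"{feature}: {len(y)} labels for {len(X)} windows")
        n_pos = int(np.sum(y != ABSENT))
        if n_pos < 100:
            msgs.append(f"{feature}: only {n_pos} positive windows (<100); "
                        "accuracy on present bins will be unreliable")
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=config.holdout_fraction, random_state=config.seed,
        )
        # Early stopping needs >= 2 classes in its validation split; a
        # degenerate all-absent target trains without it.
        early = config.early_stopping and len(np.unique(y_tr)) > 1
        clf = MLPClassifier(
            hidden_layer_sizes=HIDDEN_LAYERS,
            max_iter=config.max_iter,
            random_state=config.seed + k,
            early_stopping=early,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=config.n_iter_no_change,
            alpha=config.alpha,
            learning_rate_init=config.learning_rate_init,
            batch_size=min(config.batch_size, len(X_tr)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X_tr, y_tr)
        if not np.isfinite(clf.loss_):
            raise DetectorError(f"{feature}: training diverged (non-finite loss)")
        detectors[feature] = clf
        accuracy[feature] = float(clf.score(X_te, y_te))
    return DetectorBank(detectors, accuracy, config, msgs)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _decode_proba(clf: MLPClassifier, proba: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winning class and its probability per row."""
    classes = np.asarray(clf.classes_, dtype=int)
    if len(classes) == 1:
        # Degenerate detector trained on a single label (e.g. all-absent).
        return np.full(len(proba), classes[0]), np.ones(len(proba))
    best = np.argmax(proba, axis=1)
    return classes[best], proba[np.arange(len(proba)), best]


def detect(window: AnalysisWindow, bank: DetectorBank) -> list[DetectionCandidate]:
    """Run all six detectors on one window: exactly six candidates."""
    x = encode_window(window)[None, :]
    out = []
    for feature in FEATURES:
        clf = bank.detectors[feature]
        cls, conf = _decode_proba(clf, clf.predict_proba(x))
        bin_index = None if cls[0] == ABSENT else int(cls[0])
        out.append(DetectionCandidate(feature, bin_index, float(conf[0])))
    return out


def detect_record(
    record: PPGRecord, bank: DetectorBank
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized detection over every window of a record.

    Returns, per feature, ``(starts, classes, confidences)`` where
    ``classes`` is the decoded bin (20 = absent) for the window beginning
    at the matching start index.
    """
    X, starts = encode_record(record)
    out = {}
    for feature in FEATURES:
        clf = bank.detectors[feature]
        cls, conf = _decode_proba(clf, clf.predict_proba(X))
        out[feature] = (starts, cls, conf)
    return out


# ---------------------------------------------------------------------------
# Rule-based oracle
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def oracle_detect(record: PPGRecord) -> FeaturePointSet:
    """Deterministic fiducial detection for artifact-free records.

    W points are prominent peaks of (smoothed) vPPG at least 0.4 s apart;
    per beat, S is the PPG maximum after W, O the PPG minimum in the 0.5 s
    before W, and Z the first prominent vPPG peak after S.
    """
    ppg = record.samples
    if len(ppg) < 2 * int(HR_INTERVAL[0] * record.rate):
        raise DetectorError("record too short for beat detection")
    v = np.diff(ppg)
    vs = _smooth(v)
    amp = float(np.percentile(ppg, 98) - np.percentile(ppg, 2))
    if amp <= 0 or vs.max() <= 0:
        raise DetectorError("no beats: record has no rising pulse waves")
    w_pts, _ = find_peaks(
        vs,
        distance=int(HR_INTERVAL[0] * record.rate),
        height=0.45 * vs.max(),
        prominence=0.3 * vs.max(),
    )
    if len(w_pts) == 0:
        raise DetectorError("no beats detected")
    # Refine each W on the unsmoothed velocity.
    w_pts = np.array(
        sorted({w - 3 + int(np.argmax(v[max(0, w - 3): w + 4])) for w in w_pts})
    )
    back = int(0.5 * record.rate)
    ahead = int(0.55 * record.rate)
    beats = []
    for i, w in enumerate(w_pts):
        nxt = w_pts[i + 1] if i + 1 < len(w_pts) else len(ppg)
        s_hi = min(w + ahead, nxt, len(ppg))
        S = int(w + np.argmax(ppg[w:s_hi])) if s_hi > w else None
        # Onset foot: walk back from W to the end of the upstroke's
        # positive-velocity run (a raw argmin is unstable on the nearly
        # flat diastolic tail), then refine on the unsmoothed signal.
        o_lo = max(0, w - back)
        i = w
        while i > o_lo and vs[i - 1] > 0:
            i -= 1
        lo = max(0, i - 2)
        O = int(lo + np.argmin(ppg[lo: min(i + 3, w + 1)]))
        Z = _first_vel_peak_after(vs, S, nxt, 0.002 * amp) if S is not None else None
        beats.append(Beat(O=O, W=int(w), S=S, Z=Z, abnormal=S is None))
    return FeaturePointSet(beats=beats, noise_intervals=[])


def _first_vel_peak_after(vs: np.ndarray, start: int, stop: int, prom: float) -> int | None:
    seg = vs[start + 1: stop]
    if len(seg) < 3:
        return None
    peaks, _ = find_peaks(seg, prominence=prom)
    return int(start + 1 + peaks[0]) if len(peaks) else None


# ---------------------------------------------------------------------------
# Cross-window reconciliation
# ---------------------------------------------------------------------------

def _coverage(s: int, n_windows: int) -> int:
    """Number of sliding windows whose central region contains sample s."""
    lo = max(0, s - CENTRAL_START - DECODE_BINS + 1)
    hi = min(n_windows - 1, s - CENTRAL_START)
    return max(0, hi - lo + 1)


def coverable_region(record_length: int) -> tuple[int, int]:
    """Half-open sample range the sliding decode region can reach.

    The first 28 and last 27 samples of a record fall outside every
    window's central 0.32 s and are undetectable by construction.
    """
    return CENTRAL_START, record_length - (WINDOW_SAMPLES - CENTRAL_START - DECODE_BINS)


def _accept_positions(
    starts: np.ndarray, cls: np.ndarray, conf: np.ndarray,
    record_length: int, min_share: float = 0.5, radius: int = 1,
) -> list[tuple[int, int, float]]:
    """Vote aggregation: absolute positions backed by >=50% of the windows
    covering them (within ±1 bin), strongest support first.

    Returns ``(position, support, summed confidence)`` tuples.
    """
    n_windows = record_length - WINDOW_SAMPLES + 1
    present = cls != ABSENT
    if not np.any(present):
        return []
    pos = starts[present] + CENTRAL_START + cls[present]
    cw = conf[present]
    votes = np.zeros(record_length)
    weight = np.zeros(record_length)
    np.add.at(votes, pos, 1.0)
    np.add.at(weight, pos, cw)
    kernel = np.ones(2 * radius + 1)
    support = np.convolve(votes, kernel, mode="same")
    strength = np.convolve(weight, kernel, mode="same")
    accepted: list[tuple[int, int, float]] = []
    # Ties in ±1-bin support break toward the position actually voted for
    # (raw votes), then toward summed confidence.
    order = np.lexsort((-strength, -votes, -support))
    taken = np.zeros(record_length, dtype=bool)
    for s in order:
        if support[s] == 0:
            break
        if votes[s] == 0:
            continue
        cov = _coverage(int(s), n_windows)
        if cov == 0 or support[s] < min_share * cov:
            continue
        if taken[max(0, s - 3): s + 4].any():
            continue
        taken[s] = True
        accepted.append((int(s), int(support[s]), float(strength[s])))
    return accepted


def reconcile(
    candidates_by_window: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    record_length: int,
    rate: float = 62.5,
) -> FeaturePointSet:
    """Merge per-window detector outputs into beats and noise intervals.

    Votes from the ~20 windows covering each sample are aggregated per
    feature; W points violating the 0.4–2.0 s beat-interval constraint are
    resolved in favor of the stronger vote; beats missing O or S are
    marked abnormal; noise start/end votes are paired into half-open
    intervals (unmatched ends extend to the record boundary).
    """
    if not candidates_by_window:
        raise DetectorError("no candidates to reconcile")
    accepted = {
        f: _accept_positions(*candidates_by_window[f], record_length)
        for f in FEATURES
    }

    # Enforce the heart-rate interval on the W sequence.
    min_gap = int(round(HR_INTERVAL[0] * rate))
    ws = sorted(accepted["W"], key=lambda t: t[0])
    kept: list[tuple[int, int, float]] = []
    for w in ws:
        if kept and w[0] - kept[-1][0] < min_gap:
            if (w[1], w[2]) > (kept[-1][1], kept[-1][2]):
                kept[-1] = w
        else:
            kept.append(w)
    w_positions = [w[0] for w in kept]

    o_pos = sorted(p for p, _, _ in accepted["O"])
    s_pos = sorted(p for p, _, _ in accepted["S"])
    z_pos = sorted(p for p, _, _ in accepted["Z"])

    # Pair noise events in order; unmatched events extend to a boundary.
    events = sorted(
        [(p, "start") for p, _, _ in accepted["noise_start"]]
        + [(p, "end") for p, _, _ in accepted["noise_end"]]
    )
    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    for p, kind in events:
        if kind == "start":
            if open_start is None:
                open_start = p
        else:
            intervals.append((open_start if open_start is not None else 0, p + 1))
            open_start = None
    if open_start is not None:
        intervals.append((open_start, record_length))

    back = int(0.5 * rate)
    ahead = int(0.55 * rate)
    beats = []
    for i, w in enumerate(w_positions):
        nxt = w_positions[i + 1] if i + 1 < len(w_positions) else record_length
        O = max((p for p in o_pos if w - back <= p <= w), default=None)
        S = min((p for p in s_pos if w <= p < min(w + ahead, nxt)), default=None)
        Z = None
        if S is not None:
            Z = min((p for p in z_pos if S < p < nxt), default=None)
        overlaps_noise = any(w < e and s < nxt for s, e in intervals)
        beats.append(
            Beat(O=O, W=int(w), S=S, Z=Z,
                 abnormal=O is None or S is None or overlaps_noise)
        )
    return FeaturePointSet(beats=beats, noise_intervals=intervals)


def detect_and_reconcile(record: PPGRecord, bank: DetectorBank) -> FeaturePointSet:
    """Full network path: windows → six detectors → vote reconciliation."""
    return reconcile(detect_record(record, bank), record.n_samples, record.rate)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_detectors(bank: DetectorBank, path) -> None:
    """Serialize the bank (weights + spec + accuracies) to a JSON archive."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "spec": {"hidden_layers": list(HIDDEN_LAYERS), "outputs": DECODE_BINS + 1},
        "config": vars(bank.config) | {},
        "holdout_accuracy": bank.holdout_accuracy,
        "warnings": bank.warnings,
        "detectors": {},
    }
    payload["config"] = {k: v for k, v in bank.config.__dict__.items()}
    for feature, clf in bank.detectors.items():
        payload["detectors"][feature] = {
            "classes": [int(c) for c in clf.classes_],
            "coefs": [c.tolist() for c in clf.coefs_],
            "intercepts": [b.tolist() for b in clf.intercepts_],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_detectors(path) -> DetectorBank:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise DetectorError(f"unsupported detector archive version: {payload.get('format_version')}")
    config = TrainingConfig(**payload["config"])
    detectors = {}
    for feature, d in payload["detectors"].items():
        clf = MLPClassifier(hidden_layer_sizes=HIDDEN_LAYERS)
        clf.coefs_ = [np.array(c) for c in d["coefs"]]
        clf.intercepts_ = [np.array(b) for b in d["intercepts"]]
        clf.classes_ = np.array(d["classes"], dtype=int)
        clf.n_layers_ = len(clf.coefs_) + 1
        clf.n_outputs_ = len(clf.classes_)
        clf.n_features_in_ = clf.coefs_[0].shape[0]
        clf.out_activation_ = "softmax" if len(clf.classes_) > 2 else "logistic"
        from sklearn.preprocessing import LabelBinarizer

        clf._label_binarizer = LabelBinarizer().fit(clf.classes_)
        detectors[feature] = clf
    return DetectorBank(
        detectors,
        {k: float(v) for k, v in payload["holdout_accuracy"].items()},
        config,
        payload.get("warnings", []),
    )
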