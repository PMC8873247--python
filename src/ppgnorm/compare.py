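"""References, z-score comparison, group statistics and ROC evaluation.

A *reference* is a per-segment mean ± SD: across the ~5 sessions of one
subject (individual reference) or across the subjects of a group (group
reference).  A newly measured dataset summary is compared to a reference
through per-segment z-values

    z_i = (m_i - M_i) / SD_i,   i = 1..10,

whose mean absolute value, mean|z|, is the similarity score: small means
the measurement matches the reference.  Group-level differences are
tested per segment with

    t = (M1 - M2) / sqrt(SD1^2/n1 + SD2^2/n2)

against a one-tailed Student-t critical value; identification performance
is quantified by ROC curves and AUC (equivalently the Mann-Whitney
pairwise-concordance probability).

The two-group comparison is exposed statsmodels-style:
:class:`GroupDifferenceModel` is built from data (subject-level segment
means, references, or published summary statistics) and ``fit()`` returns
a :class:`GroupDifferenceResults` with the estimates, their pooled
standard errors, t statistics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skmetrics

from .beatnorm import DatasetSummary, N_SEGMENTS


class CompareError(ValueError):
    """Raised for unusable references or malformed comparisons."""


@dataclass(frozen=True)
class Reference:
    """Per-segment mean ± SD criterion built from n sessions or subjects."""

    label: str
    n: int
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if m.shape != (N_SEGMENTS,) or s.shape != (N_SEGMENTS,):
            raise CompareError(f"references carry exactly {N_SEGMENTS} segments")
        if np.any(s < 0):
            raise CompareError("reference SDs must be non-negative")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def usable(self) -> bool:
        """A reference with any zero SD or fewer than 2 sources cannot
        normalize differences."""
        return self.n >= 2 and bool(np.all(self.sds > 0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "n": int(self.n),
                "means": [float(x) for x in self.means],
                "sds": [float(x) for x in self.sds],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Reference":
        d = json.loads(text)
        return cls(d["label"], d["n"], np.array(d["means"]), np.array(d["sds"]))


@dataclass(frozen=True)
class ZComparison:
    """Per-segment z-values of one measurement against one reference."""

    z_values: np.ndarray
    mean_abs_z: float
    reference_label: str = ""


@dataclass(frozen=True)
class ClassificationResult:
    """Two-reference decision: the closer reference wins by mean|z|."""

    label: str
    score: float  # mean|z|(ref_b) - mean|z|(ref_a); positive favors ref_a
    tie: bool


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def build_individual_reference(summaries: list[DatasetSummary]) -> Reference:
    """Per segment: mean and sample SD of one subject's session means."""
    if len(summaries) < 2:
        raise CompareError("an individual reference needs at least 2 sessions")
    subjects = {s.subject_id for s in summaries}
    if len(subjects) != 1:
        raise CompareError(f"summaries from mixed subjects: {sorted(map(str, subjects))}")
    mat = np.stack([s.means for s in summaries])
    return Reference(
        label=str(summaries[0].subject_id),
        n=len(summaries),
        means=mat.mean(axis=0),
        sds=mat.std(axis=0, ddof=1),
    )


def build_group_reference(
    subject_means: np.ndarray | list[np.ndarray], label: str = "group"
) -> Reference:
    """Per segment: mean and sample SD across subject-level mean vectors."""
    mat = np.stack([np.asarray(m, dtype=float) for m in subject_means])
    if len(mat) < 2:
        raise CompareError("a group reference needs at least 2 subjects")
    return Reference(
        label=label, n=len(mat), means=mat.mean(axis=0), sds=mat.std(axis=0, ddof=1)
    )


# ---------------------------------------------------------------------------
# z-score comparison
# ---------------------------------------------------------------------------

def z_values(target: DatasetSummary, reference: Reference) -> ZComparison:
    """Per-segment z and the mean-|z| similarity statistic."""
    if not reference.usable:
        raise CompareError(
            f"reference {reference.label!r} is unusable (zero SD or n < 2)"
        )
    z = (target.means - reference.means) / reference.sds
    return ZComparison(z, float(np.mean(np.abs(z))), reference.label)


def classify(
    target: DatasetSummary, ref_a: Reference, ref_b: Reference
) -> ClassificationResult:
    """Assign the target to the reference with the smaller mean|z|.

    Ties break toward ``ref_a`` and are flagged.
    """
    za = z_values(target, ref_a).mean_abs_z
    zb = z_values(target, ref_b).mean_abs_z
    score = zb - za
    if score == 0:
        return ClassificationResult(ref_a.label, 0.0, True)
    return ClassificationResult(ref_a.label if score > 0 else ref_b.label, score, False)


# ---------------------------------------------------------------------------
# Group statistics (two-sample segment arithmetic)
# ---------------------------------------------------------------------------

def pooled_se(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Pooled standard error of a mean difference: sqrt(SD1²/n1 + SD2²/n2)."""
    if n1 < 1 or n2 < 1:
        raise CompareError("group sizes must be positive")
    if sd1 < 0 or sd2 < 0:
        raise CompareError("SDs must be non-negative")
    return float(np.sqrt(sd1**2 / n1 + sd2**2 / n2))


def group_t(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """t statistic of the segment-mean difference: (M1 − M2) / pooled SE."""
    se = pooled_se(sd1, n1, sd2, n2)
    if se == 0:
        raise CompareError("zero pooled SE: t statistic undefined")
    return float((m1 - m2) / se)


def t_critical(alpha: float, df: int) -> float:
    """One-tailed upper critical value of Student's t."""
    if not 0 < alpha < 1:
        raise CompareError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise CompareError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(1 - alpha, df))


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group's subject-level segment means."""

    means: np.ndarray
    sds: np.ndarray
    n: int
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))


class GroupDifferenceModel:
    """Per-segment two-group comparison of normalized PPG velocity.

    Construct from subject-level data (``from_subject_means``), from two
    group references, or directly from published summary statistics
    (``from_statistics``); ``fit`` computes mean differences, pooled SEs,
    t statistics and significance against a one-tailed critical value.

    By convention the critical value uses ``df = n2`` (the smaller
    group's size in the motivating study, printed as t_0.05,7 = 1.895);
    pass ``df`` explicitly for other conventions.
    """

    def __init__(self, group1: GroupStats, group2: GroupStats):
        if group1.means.shape != group2.means.shape:
            raise CompareError("groups must summarize the same segments")
        self.group1 = group1
        self.group2 = group2

    @classmethod
    def from_statistics(cls, m1, sd1, n1, m2, sd2, n2) -> "GroupDifferenceModel":
        return cls(GroupStats(m1, sd1, int(n1), "group1"),
                   GroupStats(m2, sd2, int(n2), "group2"))

    @classmethod
    def from_subject_means(cls, means1, means2) -> "GroupDifferenceModel":
        a = np.stack([np.asarray(m, float) for m in means1])
        b = np.stack([np.asarray(m, float) for m in means2])
        return cls(
            GroupStats(a.mean(axis=0), a.std(axis=0, ddof=1), len(a), "group1"),
            GroupStats(b.mean(axis=0), b.std(axis=0, ddof=1), len(b), "group2"),
        )

    @classmethod
    def from_references(cls, ref1: Reference, ref2: Reference) -> "GroupDifferenceModel":
        return cls(
            GroupStats(ref1.means, ref1.sds, ref1.n, ref1.label),
            GroupStats(ref2.means, ref2.sds, ref2.n, ref2.label),
        )

    def fit(self, alpha: float = 0.05, df: int | None = None) -> "GroupDifferenceResults":
        g1, g2 = self.group1, self.group2
        diffs = g1.means - g2.means
        ses = np.array([pooled_se(s1, g1.n, s2, g2.n) for s1, s2 in zip(g1.sds, g2.sds)])
        if np.any(ses == 0):
            raise CompareError("zero pooled SE in at least one segment")
        tvals = diffs / ses
        df = g2.n if df is None else df
        crit = t_critical(alpha, df)
        return GroupDifferenceResults(self, diffs, ses, tvals, alpha, df, crit)


@dataclass(frozen=True)
class GroupDifferenceResults:
    """Fitted per-segment group comparison."""

    model: GroupDifferenceModel
    mean_diff: np.ndarray
    pooled_se: np.ndarray
    tvalues: np.ndarray
    alpha: float
    df: int
    t_crit: float

    @property
    def significant(self) -> np.ndarray:
        """One-tailed significance by |t| against the critical value."""
        return np.abs(self.tvalues) > self.t_crit

    @property
    def frame(self) -> pd.DataFrame:
        g1, g2 = self.model.group1, self.model.group2
        return pd.DataFrame(
            {
                "M1": g1.means, "SD1": g1.sds,
                "M2": g2.means, "SD2": g2.sds,
                "SD12": self.pooled_se,
                "t": self.tvalues,
                "significant": self.significant,
            },
            index=pd.RangeIndex(1, len(self.mean_diff) + 1, name="segment"),
        )

    def summary(self) -> str:
        g1, g2 = self.model.group1, self.model.group2
        lines = [
            "Per-segment group comparison of normalized PPG velocity",
            f"  group 1: n = {g1.n}    group 2: n = {g2.n}    "
            f"t_crit (one-tailed, alpha={self.alpha}, df={self.df}) = {self.t_crit:.3f}",
            "",
            f"{'seg':>4} {'M1±SD1':>16} {'M2±SD2':>16} {'SD12':>7} {'t':>8}  sig",
        ]
        for i in range(len(self.mean_diff)):
            lines.append(
                f"{i + 1:>4} "
                f"{g1.means[i]:>8.3f}±{g1.sds[i]:<6.3f} "
                f"{g2.means[i]:>8.3f}±{g2.sds[i]:<6.3f} "
                f"{self.pooled_se[i]:>7.3f} {self.tvalues[i]:>8.3f}  "
                f"{'*' if self.significant[i] else ''}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """Threshold sweep: (FPR, TPR) points and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocResult:
    """ROC over similarity scores (higher score = more likely positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise CompareError("ROC needs both positive and negative examples")
    fpr, tpr, _ = _skmetrics.roc_curve(labels.astype(int), scores)
    return RocResult(fpr, tpr, float(_skmetrics.auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# Identification experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRoc:
    label: str
    auc: float
    roc: RocResult


@dataclass(frozen=True)
class IdentificationResult:
    mode: str
    per_reference: list[ReferenceRoc]
    pooled: RocResult

    @property
    def auc(self) -> float:
        return self.pooled.auc

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "auc": self.auc,
                "per_reference": [
                    {
                        "label": r.label,
                        "auc": r.auc,
                        "roc": [[float(f), float(t)] for f, t in zip(r.roc.fpr, r.roc.tpr)],
                    }
                    for r in self.per_reference
                ],
            }
        )


def identification_experiment(
    reference_summaries: dict[str, list[DatasetSummary]],
    test_summaries: list[DatasetSummary],
    groups: dict[str, str],
    mode: str,
) -> IdentificationResult:
    """Individual or group identification over a reference/test split.

    ``individual``: each subject's reference (built from their reference
    sessions) scores every test summary by −mean|z|; positives are that
    subject's own tests.  Per-reference ROCs are reported along with the
    pooled ROC over all (reference, test) pairs.

    ``group``: the two group references are built from subject-level
    reference means; each test is scored by
    mean|z|(group2) − mean|z|(group1), positives are group-1 tests.

    Reference and test sets must be disjoint.
    """
    ref_ids = {
        (s.subject_id, s.session_id) for ss in reference_summaries.values() for s in ss
    }
    test_ids = {(s.subject_id, s.session_id) for s in test_summaries}
    overlap = ref_ids & test_ids
    if overlap:
        raise CompareError(f"reference and test sets overlap: {sorted(overlap)[:3]} ...")

    individual_refs = {
        subject: build_individual_reference(ss)
        for subject, ss in reference_summaries.items()
    }

    if mode == "individual":
        per_ref, all_scores, all_labels = [], [], []
        for subject, ref in individual_refs.items():
            scores = np.array([-z_values(t, ref).mean_abs_z for t in test_summaries])
            labels = np.array([t.subject_id == subject for t in test_summaries])
            roc = roc_curve(scores, labels)
            per_ref.append(ReferenceRoc(subject, roc.auc, roc))
            all_scores.append(scores)
            all_labels.append(labels)
        pooled = roc_curve(np.concatenate(all_scores), np.concatenate(all_labels))
        return IdentificationResult("individual", per_ref, pooled)

    if mode == "group":
        by_group: dict[str, list[np.ndarray]] = {}
        for subject, ref in individual_refs.items():
            by_group.setdefault(groups[subject], []).append(ref.means)
        labels_sorted = sorted(by_group)
        if len(labels_sorted) != 2:
            raise CompareError(f"group mode needs exactly 2 groups, got {labels_sorted}")
        ref_a = build_group_reference(by_group[labels_sorted[0]], labels_sorted[0])
        ref_b = build_group_reference(by_group[labels_sorted[1]], labels_sorted[1])
        scores = np.array([classify(t, ref_a, ref_b).score for t in test_summaries])
        labels = np.array([groups[t.subject_id] == ref_a.label for t in test_summaries])
        roc = roc_curve(scores, labels)
        per_ref = [ReferenceRoc(f"{ref_a.label}|{ref_b.label}", roc.auc, roc)]
        return IdentificationResult("group", per_ref, roc)

    raise CompareError(f"unknown identification mode {mode!r}")
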