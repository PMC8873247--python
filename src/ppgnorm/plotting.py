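"""Plots of reference bands, normalized measurements and ROC curves."""

from __future__ import annotations

import numpy as np

from .beatnorm import DatasetSummary, N_SEGMENTS
from .compare import Reference, RocResult


def plot_reference_band(reference: Reference, target: DatasetSummary | None = None, ax=None):
    """Reference mean ± SD band per segment, optionally with a measurement.

    The band (upper line = M + SD, lower line = M − SD) is the visual
    criterion a new measurement is judged against.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(1, N_SEGMENTS + 1)
    ax.plot(x, reference.means + reference.sds, "r-", label="reference M + SD")
    ax.plot(x, reference.means - reference.sds, "b-", label="reference M − SD")
    if target is not None:
        ax.plot(x, target.means, "ko", label=f"measurement {target.subject_id or ''}")
    ax.set_xlabel("segment")
    ax.set_ylabel("vPPG segment value (% of beat amplitude / sample)")
    ax.set_xticks(x)
    ax.legend()
    return ax


def plot_roc(result: RocResult, label: str = "", ax=None):
    """One ROC curve with its AUC in the legend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.fpr, result.tpr, label=f"{label} AUC = {result.auc:.3f}".strip())
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend()
    return ax
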