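"""Diagnostic plots: learning curves and phase RT profiles with chunk brackets."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chunking import detect_phase_chunks, phase_rt_matrix
from .records import Cohort
from .stats import LearningCurve

_PHASE_COLORS = {"early": "tab:red", "late": "tab:blue"}


def plot_learning_curve(curve: LearningCurve, path: str | Path) -> None:
    """Mean error rate and execution time against successful-trial index."""
    trials = np.arange(1, curve.n_trials + 1)
    fig, (ax_err, ax_et) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax_err.plot(trials, curve.mean_error_rate, color="tab:gray")
    ax_err.set(xlabel="successful trial", ylabel="mean error attempts")
    ax_et.errorbar(trials, curve.mean_execution_ms, yerr=curve.sem_execution_ms,
                   fmt="-", color="tab:blue", ecolor="lightgray")
    ax_et.set(xlabel="successful trial", ylabel="execution time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rt_profiles(
    cohort: Cohort, alpha: float = 0.05, n_phase_trials: int = 10,
    path: str | Path = "rt_profiles.png", max_subjects: int = 4,
) -> None:
    """Per-subject early/late mean RT by position, chunks marked as brackets."""
    subjects = cohort[:max_subjects]
    fig, axes = plt.subplots(1, len(subjects), figsize=(4 * len(subjects), 3.4),
                             squeeze=False)
    for ax, session in zip(axes[0], subjects):
        top = 0.0
        for phase, color in _PHASE_COLORS.items():
            rt = phase_rt_matrix(session, phase, n_phase_trials)
            mean = rt.values.mean(axis=0)
            ax.plot(rt.positions, mean, color=color, label=phase)
            top = max(top, mean.max())
        for i, (phase, color) in enumerate(_PHASE_COLORS.items()):
            part = detect_phase_chunks(session, phase, alpha, n_phase_trials)
            y = top * (1.06 + 0.06 * i)
            for start, end in part.chunks:
                ax.plot([start, end], [y, y], color=color, lw=2)
                ax.plot([start, start], [y - top * 0.015, y], color=color, lw=2)
                ax.plot([end, end], [y - top * 0.015, y], color=color, lw=2)
        ax.set(title=session.subject_id, xlabel="keypress position",
               ylabel="mean RT (ms)")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
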