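"""Optional figure exports: deviation heatmap, ROC, PR, Bland–Altman,
grade-confusion heatmap. Numbers are the contract; these are conveniences."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import AgreementReport
from .measurement import DeviationMap

__all__ = [
    "plot_deviation_heatmap",
    "plot_roc",
    "plot_precision_recall",
    "plot_bland_altman",
    "plot_confusion_heatmap",
]


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_deviation_heatmap(dmap: DeviationMap, path: str | Path) -> None:
    """Occlusal-view scatter of the signed deviation map (mm)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        dmap.points[:, 0], dmap.points[:, 1], c=dmap.deviations, s=4, cmap="turbo"
    )
    fig.colorbar(sc, ax=ax, label="deviation (mm, + = removed)")
    ax.set_xlabel("mesiodistal (mm)")
    ax.set_ylabel("buccolingual (mm)")
    ax.set_aspect("equal")
    ax.set_title("Preparation depth map")
    _save(fig, path)


def plot_roc(report: AgreementReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc.x, report.roc.y, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(f"ROC (AUC = {report.roc.area:.3f})")
    _save(fig, path)


def plot_precision_recall(report: AgreementReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.pr.x, report.pr.y, drawstyle="steps-post")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_title(f"Precision–recall (AUC = {report.pr.area:.3f})")
    _save(fig, path)


def plot_bland_altman(report: AgreementReport, path: str | Path) -> None:
    ba = report.bland_altman
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(ba.means, ba.diffs, s=12)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="r", linestyle=style, lw=1)
    ax.set_xlabel("mean of panel and software score")
    ax.set_ylabel("software − panel")
    ax.set_title(
        f"Bland–Altman (bias {ba.bias:.2f}, LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}])"
    )
    _save(fig, path)


def plot_confusion_heatmap(report: AgreementReport, path: str | Path) -> None:
    mat = report.grade_confusion.matrix
    letters = report.grade_confusion.letters
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(mat, cmap="Blues")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, str(mat[i, j]), ha="center", va="center", fontsize=9)
    ax.set_xticks(range(len(letters)), letters)
    ax.set_yticks(range(len(letters)), letters)
    ax.set_xlabel("software grade")
    ax.set_ylabel("panel grade")
    fig.colorbar(im, ax=ax)
    ax.set_title("Grade confusion matrix")
    _save(fig, path)
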