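"""ROC and contour plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .roc import RocResult

__all__ = ["plot_roc", "plot_contour_measurement"]


def plot_roc(rocs: dict[str, RocResult], path=None, title="ROC"):
    """Overlay one or more empirical ROC curves with AUC annotations."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in rocs.items():
        fpr = np.concatenate([[0.0], r.fpr, [1.0]])
        tpr = np.concatenate([[0.0], r.tpr, [1.0]])
        order = np.lexsort((tpr, fpr))
        ax.plot(fpr[order], tpr[order], label=f"{name} (AUC {r.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_contour_measurement(contour, ld=None, pd_=None, path=None):
    """Cross-section polygon with the LD and PD chords drawn through it."""
    fig, ax = plt.subplots(figsize=(5, 5))
    v = np.vstack([contour.vertices, contour.vertices[:1]])
    ax.plot(v[:, 0], v[:, 1], "-", lw=1.0, color="tab:blue")
    for chord, color, name in ((ld, "tab:red", "LD"), (pd_, "tab:green", "PD")):
        if chord is not None:
            xs = [chord.p1[0], chord.p2[0]]
            ys = [chord.p1[1], chord.p2[1]]
            ax.plot(xs, ys, "-", color=color, label=f"{name} = {chord.length:.2f} mm")
    ax.set_aspect("equal")
    ax.set_xlabel("mm")
    ax.set_ylabel("mm")
    if ld is not None or pd_ is not None:
        ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
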