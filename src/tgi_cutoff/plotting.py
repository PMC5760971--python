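"""ROC curve export helpers: tidy per-threshold tables and plot files."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roc import RocCurve

__all__ = ["curve_table", "plot_roc"]


def curve_table(curve: RocCurve) -> pd.DataFrame:
    """Per-threshold operating characteristics as a tidy frame."""
    se = curve.sensitivity
    sp = curve.specificity
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = np.where(sp < 1.0, se / (1.0 - sp), np.inf)
        lr_neg = np.where(sp > 0.0, (1.0 - se) / sp, np.inf)
    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": se,
            "specificity": sp,
            "youden_j": se + sp - 1.0,
            "roc_distance": np.hypot(1.0 - se, 1.0 - sp),
            "lr_positive": lr_pos,
            "lr_negative": lr_neg,
        }
    )


def plot_roc(curve: RocCurve, path, title: str = "ROC curve", threshold: float | None = None):
    """Write a sensitivity vs 1-specificity plot to ``path`` (format by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = 1.0 - curve.specificity
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, curve.sensitivity, drawstyle="steps-post", color="C0")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    if threshold is not None:
        i = int(np.argmin(np.abs(curve.thresholds - threshold)))
        ax.plot(fpr[i], curve.sensitivity[i], "o", color="C3",
                label=f"cutoff {threshold:.2f}")
        ax.legend(loc="lower right")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
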