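"""Matplotlib renderings of the interpretability products."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .interpretability import CauseImportanceMatrix, CurveSummary

__all__ = ["plot_cause_heatmap", "plot_importance_curve"]


def plot_cause_heatmap(heat: CauseImportanceMatrix, path) -> None:
    """Cause-of-death x feature mean-importance heatmap (darker = higher)."""
    m = heat.matrix
    fig, ax = plt.subplots(figsize=(0.6 * len(m.columns) + 2,
                                    0.45 * len(m.index) + 1.5))
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap="Blues")
    ax.set_xticks(range(len(m.columns)), m.columns, rotation=45, ha="right")
    labels = [f"{idx} (n={heat.patient_counts.get(idx, 0)})"
              for idx in m.index]
    ax.set_yticks(range(len(m.index)), labels)
    fig.colorbar(im, ax=ax, label="mean attention weight")
    ax.set_title("Average feature importance by outcome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance_curve(summary: CurveSummary, path) -> None:
    """Binned mean-attention curve with knee and reference range."""
    c = summary.curve
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(c.centers, c.mean_alpha, "-o", ms=3, lw=1.5, color="tab:blue",
            label="mean attention")
    if summary.fit is not None:
        ax.plot(c.centers, summary.fit.predict(c.centers), "--",
                color="tab:orange", lw=1,
                label=f"fit (knee {summary.fit.knee:g})")
        ax.axvline(summary.fit.knee, color="tab:orange", lw=0.8, alpha=0.6)
    if summary.reference_range:
        for x in summary.reference_range:
            ax.axvline(x, ls=":", color="tab:gray", lw=1)
    ax.set_xlabel(f"{summary.feature} (raw units)")
    ax.set_ylabel("mean attention weight")
    ax.set_title(f"{summary.feature}: {summary.shape} shape, "
                 f"recommendation {summary.recommendation}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
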