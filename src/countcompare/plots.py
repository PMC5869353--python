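"""Residual-versus-fit panel plots, one row per route."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .comparison import ComparisonReport

__all__ = ["plot_residual_panels"]

_LABELS = {
    "sqrt_lm": "LM on sqrt-transformed y",
    "log_lm": "LM on log-transformed y",
    "glm": "GLM (log link)",
}


def plot_residual_panels(report: ComparisonReport, path: str | Path) -> None:
    """Stacked residual-vs-fit panels (sqrt LM, log LM, GLM) with smooths."""
    fig, axes = plt.subplots(3, 1, figsize=(5, 9), sharex=False)
    for ax, route in zip(axes, ("sqrt_lm", "log_lm", "glm")):
        diag = report.routes[route].diagnostics
        ax.scatter(diag.fitted, diag.residuals, s=18, color="black", alpha=0.7)
        if len(diag.smooth_curve):
            ax.plot(diag.smooth_curve[:, 0], diag.smooth_curve[:, 1], color="red", lw=1.5)
        ax.axhline(0.0, color="gray", lw=0.8, ls="--")
        ax.set_title(f"{_LABELS[route]}  (fan index {diag.fan_index:+.2f})", fontsize=10)
        ax.set_xlabel("fitted")
        ax.set_ylabel(f"{diag.residual_type} residual")
    fig.suptitle(report.dataset_id, fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
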