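"""Plot exports for the rendered report (applicability heatmap,
limit-annotated histograms, margins plots).  All figures are written
as files; nothing is shown interactively."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_VERDICT_COLORS = {
    "applicable": 0,
    "no-metadata": 1,
    "no-data": 2,
    "type-mismatch": 3,
}


def applicability_heatmap(matrix, path: Path) -> None:
    """Heatmap-like overview of which checks can run on which variable."""
    frame = matrix.frame
    grid = np.array(
        [[_VERDICT_COLORS[v] for v in row] for _, row in frame.iterrows()]
    )
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.5 * len(frame.columns), 1.0 + 0.3 * len(frame))
    )
    cmap = matplotlib.colors.ListedColormap(
        ["#4daf4a", "#cccccc", "#ffffff", "#e41a1c"]
    )
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=3, aspect="auto")
    ax.set_xticks(range(len(frame.columns)), frame.columns,
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(frame)), frame.index, fontsize=7)
    ax.set_title("Check applicability")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def limit_histogram(result, path: Path) -> None:
    """Histogram of a variable with its limit positions marked."""
    desc = result.descriptor or {}
    hist = desc.get("histogram")
    if not hist:
        return
    edges = np.asarray(hist["edges"])
    counts = np.asarray(hist["counts"])
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="#7799cc", edgecolor="white")
    if "limits" in desc:
        from .core_model import parse_interval

        iv = parse_interval(desc["limits"])
        for bound in (iv.lower, iv.upper):
            if np.isfinite(float(bound)):
                ax.axvline(float(bound), color="#e41a1c", linestyle="--")
    ax.set_title(f"{result.variable} ({result.indicator_id})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def margins_plot(result, path: Path) -> None:
    """Per-class adjusted means with CIs against the overall mean."""
    desc = result.descriptor or {}
    pc = desc.get("per_class")
    if not pc:
        return
    classes = [str(c) for c in pc["class"]]
    means = np.asarray(pc["mean"], dtype=float)
    lo = np.asarray(pc["ci_low"], dtype=float)
    hi = np.asarray(pc["ci_high"], dtype=float)
    x = np.arange(len(classes))
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.errorbar(x, means, yerr=[means - lo, hi - means], fmt="o",
                color="#333333", capsize=3)
    ax.axhline(desc["overall_adjusted_mean"], color="#e41a1c",
               linestyle="--", label="overall adjusted mean")
    flagged = set(desc.get("flagged_classes", []))
    for xi, c in zip(x, classes):
        if c in flagged:
            ax.scatter([xi], [means[xi]], color="#e41a1c", zorder=5)
    ax.set_xticks(x, classes)
    ax.set_xlabel(desc.get("class_var", "class"))
    ax.set_title(f"{desc.get('response', result.variable)} adjusted margins",
                 fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
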