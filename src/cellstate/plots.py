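"""Diagnostic plots: per-class reliability curves and certainty densities."""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def _axes(n_panels: int):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ncols = min(4, n_panels)
    nrows = int(np.ceil(n_panels / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows),
                             squeeze=False)
    return fig, axes.ravel()


def plot_reliability(results, path=None):
    """One reliability panel per class: mean predicted probability vs the
    observed positive fraction in 10 equal-width bins."""
    rel = results.training_report.get("calibration", {}).get("reliability")
    if not rel:
        raise ValidationError("no calibration curves in the training report")
    fig, axes = _axes(len(rel))
    for ax, (cls, rows) in zip(axes, rel.items()):
        xs = [r["mean_prob"] for r in rows if r["count"] > 0]
        ys = [r["frac_positive"] for r in rows if r["count"] > 0]
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(xs, ys, "o-", ms=3)
        ax.set_title(str(cls), fontsize=8)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    for ax in axes[len(rel):]:
        ax.set_visible(False)
    fig.suptitle("Per-class reliability")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return fig


def plot_certainty_density(summary: dict, path=None):
    """Cumulative certainty-density curve with the low/medium/high bin
    thresholds marked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cum = summary["cumulative_density"]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(cum["cumulative_fraction"], cum["certainty"], lw=1.2)
    for tau in (0.3, 0.7):
        ax.axhline(tau, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("cumulative fraction of cells")
    ax.set_ylabel("certainty score")
    ax.set_ylim(0, 1)
    pct = summary["percentages"]
    ax.set_title(
        f"low {pct['low']:.1f}% / medium {pct['medium']:.1f}% / "
        f"high {pct['high']:.1f}%",
        fontsize=9,
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
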