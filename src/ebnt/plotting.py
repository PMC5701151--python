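"""Simple diagnostic plots (not publication figures)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .connectivity import ConnectivityMatrix  # noqa: E402

__all__ = ["plot_connectivity_matrix", "plot_density_curves"]


def plot_connectivity_matrix(cm: ConnectivityMatrix, path: str) -> None:
    """Heatmap of one subject x band PLI matrix."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cm.matrix, vmin=0, vmax=max(1e-9, cm.matrix.max()),
                   cmap="viridis")
    ax.set_title(f"{cm.subject_id} / {cm.band} PLI")
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    fig.colorbar(im, ax=ax, label="PLI")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_density_curves(metrics: pd.DataFrame, band: str, measure: str,
                        path: str) -> None:
    """Group mean +/- s.e. of a binary metric as a function of link
    density."""
    sub = metrics[(metrics["band"] == band)
                  & (metrics["measure"] == measure)
                  & metrics["density"].notna()]
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, g in sub.groupby("group"):
        agg = g.groupby("density")["value"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"],
                    label=f"group {group}", capsize=2)
    ax.set_xlabel("link density")
    ax.set_ylabel(measure)
    ax.set_title(f"{measure} vs density ({band})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
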