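"""Minimal plotting: Manhattan view of the linearized genome scan."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_COLORS = {"miRNA": "#1f77b4", "mRNA": "#d62728", "protein": "#2ca02c"}
_SIZES = {"miRNA": 24.0, "mRNA": 6.0, "protein": 10.0}


def plot_manhattan(table: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Scatter -log10 adjusted p against global genomic position.

    One dot per feature, colored by omics kind; miRNA dots are drawn larger
    since they are far fewer. A dashed line marks the significance level.
    """
    fig, ax = plt.subplots(figsize=(10, 4))
    for kind, sub in table.groupby("omics_kind"):
        ax.scatter(
            sub["global_position"],
            sub["neg_log10_adj_p"],
            s=_SIZES.get(kind, 8.0),
            c=_COLORS.get(kind, "gray"),
            label=kind,
            linewidths=0,
        )
    ax.axhline(-np.log10(alpha), color="black", linestyle="--", linewidth=0.8)
    ax.set_xlabel("genomic position (chromosomes 1..22, X, Y concatenated)")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
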