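"""Minimal diagnostic plots: CQ histogram and repeat accumulation profile."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np


def cq_histogram(records: Sequence, path: str | Path, max_cq: float = 3.0) -> None:
    """Histogram of defined CQ values with the X and Y decision bands shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.array([r.cq for r in records if r.cq == r.cq])  # drop nan
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(np.clip(values, 0, max_cq), bins=120, color="0.4")
    ax.axvspan(0, 0.05, color="tab:blue", alpha=0.2, label="Y band")
    ax.axvspan(1.9, 2.5, color="tab:red", alpha=0.2, label="X band")
    ax.set_xlabel("chromosome quotient (female/male alignment ratio)")
    ax.set_ylabel("contigs")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def landscape_profile(table, path: str | Path) -> None:
    """Stacked bar profile of repeat bp versus percent divergence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(df))
    for column in df.columns:
        ax.bar(df.index, df[column], width=table.bin_width, bottom=bottom,
               align="edge", label=str(column))
        bottom += df[column].to_numpy()
    ax.set_xlabel("Kimura 2-parameter divergence from consensus (%)")
    ax.set_ylabel("aligned repeat bp")
    if len(df.columns):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
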