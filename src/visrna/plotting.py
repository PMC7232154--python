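"""Optional matplotlib figures: size distributions, strand-resolved genome
profiles and positional nucleotide-frequency heat maps.

Positive-strand signal is drawn upward in yellow-orange, negative-strand
signal downward in blue, the usual convention for strand-split small-RNA
coverage panels.  All functions take an output path and write PDF/PNG based
on the suffix; they import nothing at module level beyond matplotlib with
the Agg backend, so they are safe headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .profiles import CoverageProfile
from .signature import RNA_BASES, FrequencyMatrix

POSITIVE_COLOR = "#E8A33D"
NEGATIVE_COLOR = "#3D6FE8"


def plot_size_distribution(df: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Bar plot of per-length read counts (strand-split when available)."""
    fig, ax = plt.subplots(figsize=(5, 3))
    lengths = df.index.to_numpy()
    if {"plus", "minus"} <= set(df.columns):
        ax.bar(lengths, df["plus"], color=POSITIVE_COLOR, label="+ strand")
        ax.bar(lengths, -df["minus"], color=NEGATIVE_COLOR, label="- strand")
        ax.axhline(0, color="black", linewidth=0.5)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.bar(lengths, df["count"], color="gray")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("reads")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_coverage(profile: CoverageProfile, path: str | Path, title: str = "") -> None:
    """Strand-split positional profile with gene annotations, if present."""
    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(profile.plus))
    ax.fill_between(x, profile.plus, step="mid", color=POSITIVE_COLOR, label="+ strand")
    ax.fill_between(x, -profile.minus, step="mid", color=NEGATIVE_COLOR, label="- strand")
    ax.axhline(0, color="black", linewidth=0.5)
    ymax = max(1, int(profile.plus.max()), int(profile.minus.max()))
    for label, start, end in profile.annotations:
        ax.axvspan(start, end, color="gray", alpha=0.12)
        ax.text(
            (start + end) / 2, ymax * 1.02, label, ha="center", fontsize=6, rotation=45
        )
    ax.set_xlabel(f"{profile.virus} position (nt)")
    lo, hi = profile.length_class
    ax.set_ylabel(f"{lo}-{hi} nt 5' ends" if lo != hi else f"{lo} nt 5' ends")
    ax.legend(frameon=False, fontsize=8, loc="lower right")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_frequency_heatmap(
    matrix: FrequencyMatrix, path: str | Path, title: str = ""
) -> None:
    """Per-position nucleotide-frequency heat map with 1U/10A markers."""
    fig, ax = plt.subplots(figsize=(6, 2.2))
    freq = matrix.frequencies.T  # bases x positions
    im = ax.imshow(freq, aspect="auto", cmap="Blues", vmin=0, vmax=1)
    ax.set_yticks(range(4), RNA_BASES)
    ax.set_xticks(
        range(0, matrix.max_len, 5), [str(p + 1) for p in range(0, matrix.max_len, 5)]
    )
    ax.set_xlabel("position from 5' end (nt)")
    # arrowheads at the canonical bias positions
    ax.annotate(
        "", xy=(0, -0.6), xytext=(0, -1.6), arrowprops=dict(arrowstyle="-|>", color="black")
    )
    ax.annotate(
        "", xy=(9, -0.6), xytext=(9, -1.6), arrowprops=dict(arrowstyle="-|>", color="red")
    )
    fig.colorbar(im, ax=ax, label="frequency")
    ax.set_title(title or f"{matrix.class_label} {matrix.strand} strand", fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
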