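"""Diagnostic plots: LRR/BAF tracks and arm fold-change profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .expr_cnv import ArmFCResult


def plot_lrr_baf(
    probes: pd.DataFrame,
    path: str | Path,
    title: str = "",
    highlight: Optional[tuple[int, int]] = None,
) -> None:
    """Two-panel LRR/BAF scatter along one chromosome, the view used to
    adjudicate candidate CNV calls by eye."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    ax1.plot(probes["pos"], probes["lrr"], ".", ms=2, color="0.3")
    ax1.axhline(0.0, color="k", lw=0.5)
    ax1.set_ylabel("LRR")
    ax2.plot(probes["pos"], probes["baf"], ".", ms=2, color="0.3")
    ax2.set_ylabel("BAF")
    ax2.set_xlabel("position (bp)")
    if highlight:
        for ax in (ax1, ax2):
            ax.axvspan(highlight[0], highlight[1], color="red", alpha=0.15)
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_arm_contrast(result: ArmFCResult, path: str | Path) -> None:
    """Replicate log2 fold change vs genomic position with per-arm means,
    the view in which a single-replicate arm duplication stands out."""
    fig, ax = plt.subplots(figsize=(10, 4))
    fc = result.fc
    ax.plot(fc["start"], fc["fc"], ".", ms=3, color="0.4")
    ax.axhline(0.0, color="k", ls=":", lw=1)
    for arm, color in (("p", "red"), ("q", "green")):
        sub = fc[fc["arm"] == arm]
        if sub.empty:
            continue
        ax.hlines(
            sub["fc"].mean(), sub["start"].min(), sub["start"].max(),
            color=color, lw=2, label=f"{arm}-arm mean",
        )
    ax.set_xlabel(f"chromosome {result.chrom} position (bp)")
    ax.set_ylabel("log2 fold change (A / B)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
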