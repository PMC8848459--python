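"""Figure helpers mirroring the standard displays of this workflow."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ancestry import AncestryProfile
from .delimit import DistortionReport
from .dstats import FBranchMatrix


def ancestry_barplot(
    profile: AncestryProfile,
    order: Optional[Sequence[str]] = None,
    ax=None,
):
    """Stacked per-specimen ancestry bars, specimens in the given order
    (typically sorted by clade then by maximum ancestry)."""
    q = profile.Q
    if order is not None:
        q = q.loc[list(order)]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.12 * len(q)), 2.5))
    bottom = np.zeros(len(q))
    for col in q.columns:
        ax.bar(range(len(q)), q[col], bottom=bottom, width=1.0, label=col)
        bottom += q[col].to_numpy()
    ax.set_xlim(-0.5, len(q) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    ax.set_xticks([])
    ax.legend(fontsize=6, ncol=min(len(q.columns), 6))
    return ax


def fbranch_heatmap(matrix: FBranchMatrix, masked_only: bool = True, ax=None):
    """Branch x donor heatmap; by default only cells passing the display
    rule (value above threshold and significant) are shown."""
    vals = matrix.values.copy()
    if masked_only:
        vals = vals.where(matrix.display)
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.4 * vals.shape[1], 1 + 0.3 * vals.shape[0])
        )
    im = ax.imshow(vals.to_numpy(dtype=float), cmap="viridis", vmin=0, aspect="auto")
    ax.set_xticks(range(vals.shape[1]), vals.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=6)
    ax.set_xlabel("donor")
    ax.set_ylabel("recipient branch")
    plt.colorbar(im, ax=ax, label="f-branch")
    return ax


def distortion_scatter(report: DistortionReport, axes=None):
    """Scatter(s): terminal gCF vs q_max and/or I_PDA vs SD(q_max)."""
    panels = []
    if report.per_specimen is not None and len(report.per_specimen):
        panels.append("envelope")
    if report.per_candidate is not None and len(report.per_candidate):
        panels.append("imbalance")
    if axes is None:
        _, axes = plt.subplots(1, max(len(panels), 1), figsize=(5 * len(panels), 4))
        if len(panels) == 1:
            axes = [axes]
    for ax, panel in zip(np.atleast_1d(axes), panels):
        if panel == "envelope":
            t = report.per_specimen
            ax.scatter(t["q_max"], t["terminal_gcf"], s=12, alpha=0.6)
            if report.envelope is not None and not report.envelope.skipped:
                ax.plot(
                    report.envelope.bin_centers,
                    report.envelope.bin_max_gcf,
                    "r--",
                    label="bin max",
                )
                ax.legend()
            ax.set_xlabel("maximum individual ancestry")
            ax.set_ylabel("terminal gCF (%)")
        else:
            t = report.per_candidate
            ax.scatter(t["sd_qmax"], t["i_pda"], s=20)
            if report.regression is not None and not report.regression.undefined:
                x = np.linspace(t["sd_qmax"].min(), t["sd_qmax"].max(), 10)
                ax.plot(
                    x,
                    report.regression.intercept + report.regression.slope * x,
                    "r-",
                    label=f"R2={report.regression.r_squared:.2f}",
                )
                ax.legend()
            ax.set_xlabel("SD of maximum individual ancestry")
            ax.set_ylabel("Colless I (PDA-normalized)")
    return axes
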