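"""Bar-plot reports: per-muscle medians with per-subject signed differences."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import CohortTable
from .stats import limb_comparison


def plot_limb_comparison(
    cohort: CohortTable,
    quantity: str,
    path: str | Path,
    denominator: str = "right",
) -> None:
    """Two-panel figure: right/left medians (min-max whiskers) per muscle on
    top, per-subject signed percentage differences as grouped bars below."""
    results = limb_comparison(cohort, quantity, denominator=denominator)
    if not results:
        return
    muscles = sorted(results)
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(max(8, 0.6 * len(muscles)), 7), sharex=True
    )
    x = np.arange(len(muscles))
    for offset, side, col in ((-0.2, "right", "median_a"), (0.2, "left", "median_b")):
        med = [getattr(results[m], col) for m in muscles]
        ax1.bar(x + offset, med, width=0.38, label=side)
    for m, xi in zip(muscles, x):
        star = "*" if results[m].p_value < 0.05 else ""
        if star:
            ax1.annotate(star, (xi, ax1.get_ylim()[1] * 0.95), ha="center")
    ax1.set_ylabel(f"median {quantity}")
    ax1.legend()
    for xi, m in zip(x, muscles):
        d = results[m].diffs_pct
        w = 0.8 / max(len(d), 1)
        pos = xi - 0.4 + w * (np.arange(len(d)) + 0.5)
        ax2.bar(pos, d, width=w, color=np.where(d >= 0, "tab:blue", "tab:red"))
    ax2.axhline(0.0, color="k", lw=0.5)
    ax2.set_ylabel("right-left difference (%)")
    ax2.set_xticks(x)
    ax2.set_xticklabels(muscles, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
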