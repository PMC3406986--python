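"""Figure exports: cumulative-effect bar charts and effect histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .effects import EffectSize
from .epistasis import SUBSETS, CumulativeEffect


def cumulative_bar_chart(rows: Sequence[CumulativeEffect], path) -> Path:
    """Rank-ordered |cumulative effect| per trait, one panel per subset,
    with the 100% additivity reference line; epistatic traits in red."""
    path = Path(path)
    fig, axes = plt.subplots(1, len(SUBSETS), figsize=(12, 4), sharey=True)
    for ax, subset in zip(axes, SUBSETS):
        sub = sorted(
            (r for r in rows if r.subset == subset and not r.empty),
            key=lambda r: abs(r.sum_percent),
            reverse=True,
        )
        values = [abs(r.sum_percent) for r in sub]
        colors = ["#c0392b" if r.epistatic else "#7f8c8d" for r in sub]
        ax.bar(range(len(sub)), values, color=colors)
        ax.axhline(100.0, linestyle="--", color="black", linewidth=1)
        ax.set_title(subset)
        ax.set_xlabel("trait rank")
    axes[0].set_ylabel("|cumulative effect| (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def effect_histogram(effects: Sequence[EffectSize], path, bins: int = 25) -> Path:
    """Frequency distribution of NormUnit effects, significant (red) vs
    non-significant (blue) strata; host sits at 0%, donor at 100%."""
    path = Path(path)
    sig = [e.norm_unit for e in effects if e.significant]
    nonsig = [e.norm_unit for e in effects if not e.significant]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(
        [sig, nonsig],
        bins=bins,
        stacked=True,
        color=["#c0392b", "#2980b9"],
        label=["significant", "non-significant"],
    )
    ax.axvline(0.0, color="black", linewidth=1)
    ax.axvline(100.0, color="black", linewidth=1, linestyle="--")
    ax.set_xlabel("effect (% of parental difference)")
    ax.set_ylabel("CSS-trait pairs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
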