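"""Report figures for windowed population statistics."""
from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_stage_stats"]


def plot_stage_stats(stats, out_path) -> None:
    """Two-panel summary: event frequencies per stage window, and the
    population (n at window start) with mean diameter."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    x = stats.window
    for col, style, label in (("fl_ratio", "g.-", "FL frequency"),
                              ("od_event_freq", "r.-", "OD formation"),
                              ("death_freq", "k.--", "death frequency"),
                              ("single_ratio", "b.-", "single fraction")):
        if col in stats and stats[col].notna().any():
            ax1.plot(x, stats[col], style, label=label)
    ax1.set_xticks(x)
    ax1.set_xticklabels(stats.label, rotation=45, ha="right", fontsize=8)
    ax1.set_ylabel("fraction of oocytes at window start")
    ax1.legend(fontsize=8)

    ax2.bar(x, stats.n_start, color="0.8", label="oocytes at window start")
    ax2.set_ylabel("n at window start")
    if "mean_diameter" in stats:
        ax3 = ax2.twinx()
        ax3.errorbar(x, stats.mean_diameter, yerr=stats.sd_diameter,
                     fmt="m.-", label="diameter")
        ax3.set_ylabel("mean diameter (um)")
    ax2.set_xticks(x)
    ax2.set_xticklabels(stats.label, rotation=45, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
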