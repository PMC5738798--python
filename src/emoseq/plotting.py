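"""Bar charts of group mean ranked ARFs with standard-error whiskers."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_mean_ranks(summary: pd.DataFrame, out_path: str | Path) -> Path:
    """Grouped bar chart: one cluster per sequence key, one bar per group,
    bar height = mean ranked ARF, whisker = standard error.

    ``summary`` is the frame produced by
    :func:`emoseq.group_stats.summarize_mean_ranks`.
    """
    keys = list(dict.fromkeys(summary["key"]))
    groups = list(dict.fromkeys(summary["group"]))
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(max(6.0, 1.1 * len(keys)), 4.0))
    for gi, g in enumerate(groups):
        sub = summary[summary["group"] == g].set_index("key").reindex(keys)
        x = [i + gi * width for i in range(len(keys))]
        ax.bar(x, sub["mean_rank"], width=width, yerr=sub["se"], capsize=2, label=g)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(keys))])
    ax.set_xticklabels(keys, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("mean ranked ARF")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
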