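"""Stacked-bar class summaries (percent decreased / increased / unchanged).

One bar per ncRNA class per KO contrast, segmented into the percentage of
expressed features that are decreased, increased or unchanged relative to
WT, with an asterisk over classes whose decreased-vs-not split differs from
the miRNA class at p < 1e-4 (two-sided exact test).  Every number plotted
is also written to a TSV; nothing lives only in the figure.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 1e-4

_SEGMENTS = [  # (column, legend label, colour) — decreased blue, increased red
    ("pct_down", "decreased", "#3b6fb5"),
    ("pct_up", "increased", "#c23b3b"),
    ("pct_unchanged", "unchanged", "#e8932f"),
]

_CLASS_ORDER = ["miRNA", "yRNA", "tRNA", "rRNA", "snoRNA", "snRNA", "other"]


def render_summary(
    summaries: pd.DataFrame,
    *,
    tsv_path: str | Path,
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the numeric class-summary TSV and (optionally) the figure.

    ``summaries`` concatenates :func:`sncfrag.diffexp.summarize_classes`
    outputs over one or more KO contrasts.  The TSV always carries exactly
    the plotted percentages and p-values.
    """
    if summaries is None or summaries.empty:
        raise ValueError("no class summaries to render")
    summaries = summaries.copy()
    summaries["significant_vs_mirna"] = (
        summaries["p_down_vs_mirna"] < SIGNIFICANCE_LEVEL
    ) & (summaries["class_label"] != "miRNA")
    summaries.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")

    if summaries["class_label"].nunique() < 2:
        logger.warning("single ncRNA class: no between-class significance marks")

    if figure_path is None:
        return summaries

    kos = list(dict.fromkeys(summaries["ko_name"]))
    fig, axes = plt.subplots(
        1, len(kos), figsize=(1.0 + 2.2 * len(kos), 3.6), squeeze=False, sharey=True
    )
    for ax, ko in zip(axes[0], kos):
        sub = summaries[summaries["ko_name"] == ko]
        order = [c for c in _CLASS_ORDER if c in set(sub["class_label"])]
        order += [c for c in sub["class_label"] if c not in order]
        sub = sub.set_index("class_label").loc[order]
        bottom = pd.Series(0.0, index=sub.index)
        for col, label, color in _SEGMENTS:
            ax.bar(sub.index, sub[col], bottom=bottom, color=color, label=label,
                   width=0.7)
            bottom += sub[col]
        for i, label in enumerate(sub.index):
            if bool(sub.loc[label, "significant_vs_mirna"]):
                ax.text(i, 101, "*", ha="center", va="bottom", fontsize=14)
        ax.set_title(f"{ko} vs WT", fontsize=10)
        ax.set_ylim(0, 112)
        ax.set_ylabel("% of expressed features")
        ax.tick_params(axis="x", rotation=45)
    axes[0][-1].legend(fontsize=8, loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
    return summaries
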