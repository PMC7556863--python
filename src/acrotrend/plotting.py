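"""Static figures for trend and word-count series."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .trends import AnnualTrend  # noqa: E402


def plot_annual_trends(series: Mapping[str, Sequence[AnnualTrend]],
                       out_path: str | None = None):
    """One panel per field: mean acronym density per 100 words by year,
    with per-length strata overlaid when present."""
    fields = list(series)
    fig, axes = plt.subplots(1, len(fields), figsize=(6 * len(fields), 4),
                             squeeze=False)
    for ax, field in zip(axes[0], fields):
        trends = series[field]
        years = [t.year for t in trends]
        ax.plot(years, [t.mean_density for t in trends],
                color="purple", label="all acronyms")
        for stratum, color in ((2, "tab:orange"), (3, "tab:blue"),
                               (4, "olive")):
            key = ("length", stratum)
            if any(key in t.strata for t in trends):
                ax.plot(years, [t.strata.get(key, 0.0) for t in trends],
                        color=color, label=f"length {stratum}")
        ax.set_title(field)
        ax.set_xlabel("year")
        ax.set_ylabel("acronyms per 100 words")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_word_counts(series: Mapping[str, Sequence[tuple[int, float]]],
                     out_path: str | None = None):
    """Mean words per paper by year, one panel per field; axes are free
    because the relative trend, not the absolute level, is the message."""
    fields = list(series)
    fig, axes = plt.subplots(1, len(fields), figsize=(6 * len(fields), 4),
                             squeeze=False)
    for ax, field in zip(axes[0], fields):
        pts = series[field]
        ax.plot([y for y, _ in pts], [w for _, w in pts], color="teal")
        ax.set_title(field)
        ax.set_xlabel("year")
        ax.set_ylabel("mean words")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
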