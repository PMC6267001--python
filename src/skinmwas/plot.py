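"""Best-effort plotting helpers (ordination biplot, odor summaries)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordination import CapResult  # noqa: E402


def cap_biplot(result: CapResult, meta, ax=None):
    """Constrained-ordination biplot: dots sized by odor intensity, labeled
    by timepoint, with constraint arrows."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores = result.sample_scores
    axes = list(scores.columns[:2])
    if len(axes) < 2:
        raise ValueError("need at least two constrained axes for a biplot")
    m = meta.set_index("sample_id").loc[scores.index]
    size = 10 + 2.0 * m["odor_intensity"]
    colors = m["age_group"].map({"children": "tab:blue", "teens": "tab:orange"})
    ax.scatter(scores[axes[0]], scores[axes[1]], s=size, c=colors, alpha=0.6,
               edgecolor="none")
    for sid, row in scores.iterrows():
        ax.annotate(str(m.loc[sid, "timepoint"]).rstrip("h"),
                    (row[axes[0]], row[axes[1]]), fontsize=6, ha="center",
                    va="center")
    span = float(scores[axes].abs().to_numpy().max())
    for name, row in result.biplot_scores.iterrows():
        ax.annotate(name, xy=(row[axes[0]] * span, row[axes[1]] * span),
                    xytext=(0, 0), textcoords="data", color="tab:red",
                    arrowprops=dict(arrowstyle="<-", color="tab:red", lw=1))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(axes[0])
    ax.set_ylabel(axes[1])
    return ax
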