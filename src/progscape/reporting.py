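"""Figure/table emission for evaluation landscapes.

The tab-separated long table written by :meth:`LandscapeResult.write` is the
contract; heatmaps are a convenience rendering of the same numbers. Failed
("grey") cells are drawn hatched with no number.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402
import seaborn as sns  # noqa: E402

from .evaluate import LandscapeResult  # noqa: E402

__all__ = ["plot_landscape_heatmaps", "landscape_from_long"]

_METRIC_STYLE = {
    "ci": dict(cmap="RdBu_r", center=0.5, vmin=0.3, vmax=1.0,
               title="Concordance index"),
    "kappa": dict(cmap="PuOr_r", center=0.0, vmin=-0.2, vmax=1.0,
                  title="Fleiss kappa"),
    "size": dict(cmap="mako_r", center=None, vmin=None, vmax=None,
                 title="Average model size"),
}


def plot_landscape_heatmaps(landscape: LandscapeResult, outdir) -> list[Path]:
    """Write one heatmap PNG per metric; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {"ci": landscape.ci, "kappa": landscape.kappa,
              "size": landscape.size}
    paths = []
    for metric, table in tables.items():
        style = _METRIC_STYLE[metric]
        h = max(2.0, 0.45 * len(table.index) + 1.5)
        w = max(3.0, 0.9 * len(table.columns) + 2.0)
        fig, ax = plt.subplots(figsize=(w, h))
        sns.heatmap(table, annot=True, fmt=".2f", cmap=style["cmap"],
                    center=style["center"], vmin=style["vmin"],
                    vmax=style["vmax"], linewidths=0.5, linecolor="white",
                    cbar_kws={"label": style["title"]}, ax=ax)
        for i, cohort in enumerate(table.index):
            for j, model in enumerate(table.columns):
                if landscape.failed.loc[cohort, model]:
                    ax.add_patch(plt.Rectangle((j, i), 1, 1, fill=True,
                                               color="lightgrey",
                                               hatch="//", zorder=3))
        ax.set_title(style["title"])
        ax.set_xlabel("model")
        ax.set_ylabel("cohort")
        fig.tight_layout()
        path = outdir / f"landscape_{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths


def landscape_from_long(path) -> dict[str, pd.DataFrame]:
    """Read a landscape long table back into wide metric tables (for the
    ``report`` subcommand; loses per-cell fold detail)."""
    long = pd.read_csv(path, sep="\t")
    out = {}
    for metric in ("ci", "kappa", "size"):
        sub = long[long["metric"] == metric]
        out[metric] = sub.pivot(index="cohort", columns="model",
                                values="value")
    out["failed"] = (long[long["metric"] == "ci"]
                     .pivot(index="cohort", columns="model", values="failed")
                     .astype(bool))
    return out
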