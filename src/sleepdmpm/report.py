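"""Rendering of contrast results as report tables and forest-style plots.

Every number rendered here is read straight from a
:class:`~sleepdmpm.do_contrast.ContrastResult` summary — nothing is
recomputed at render time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .do_contrast import CATEGORY_ORDER, ContrastResult

__all__ = ["render_summary", "summary_table", "forest_plot"]

OUTCOME_ORDER = ("y1=1", "y2=1", "y2=3", "y3=1", "y3=3")
OUTCOME_LABELS = {
    "y1=1": "Daytime sleepiness = 1",
    "y2=1": "Fall asleep = 1",
    "y2=3": "Fall asleep = 3",
    "y3=1": "Waking up = 1",
    "y3=3": "Waking up = 3",
}


def summary_table(result: "ContrastResult | pd.DataFrame") -> pd.DataFrame:
    """Category x outcome table of ``mean [5%, 95%]`` strings (one subsample).

    Accepts a :class:`ContrastResult` or its saved tidy summary frame.
    Categories appear in the fixed report order with the AR(1) row last;
    a category absent from the result is marked ``"absent"`` rather than
    dropped.
    """
    df = result if isinstance(result, pd.DataFrame) else result.summary_frame()
    df = df.copy()
    df["item"] = df["item"].fillna("")
    cat_rows = df[df["item"] == ""]
    table = pd.DataFrame(index=list(CATEGORY_ORDER), columns=list(OUTCOME_ORDER),
                         dtype=object)
    table[:] = "absent"
    for _, row in cat_rows.iterrows():
        table.loc[str(row["category"]), row["outcome"]] = (
            f"{row['posterior_mean']:.3f} [{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
        )
    table.index.name = "category"
    return table


def render_summary(results: "dict[str, ContrastResult | pd.DataFrame]") -> str:
    """Text report over subsamples, mirroring the four-panel figure layout
    (males/females x summer/winter), one table per subsample."""
    if not results:
        raise ValueError("no contrast results to render")
    blocks = []
    for name, res in results.items():
        table = summary_table(res)
        header = f"== {name} ==  (posterior mean [90% CI] of |dPr|)"
        blocks.append(header + "\n" + table.to_string())
    return "\n\n".join(blocks) + "\n"


def forest_plot(results: dict[str, ContrastResult], path) -> None:
    """Forest-style panel figure: one subplot per subsample, categories on
    the vertical axis, one marker+interval per outcome target."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False, sharey=True)
    cats = list(CATEGORY_ORDER)[::-1]
    ypos = np.arange(len(cats))
    for ax, (name, res) in zip(axes[0], results.items()):
        df = res.summary_frame()
        cat_rows = df[df["item"] == ""].set_index(["category", "outcome"])
        for k, okey in enumerate(OUTCOME_ORDER):
            offs = (k - 2) * 0.14
            means, los, his, ys = [], [], [], []
            for i, cat in enumerate(cats):
                try:
                    row = cat_rows.loc[(cat, okey)]
                except KeyError:
                    continue
                means.append(row["posterior_mean"])
                los.append(row["posterior_mean"] - row["ci_low"])
                his.append(row["ci_high"] - row["posterior_mean"])
                ys.append(i + offs)
            ax.errorbar(means, ys, xerr=[los, his], fmt="o", ms=3, lw=1,
                        label=OUTCOME_LABELS[okey])
        ax.set_yticks(ypos, cats)
        ax.set_xlabel("|dPr| per IQR improvement")
        ax.set_title(name)
    axes[0][0].legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
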