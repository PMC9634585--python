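"""Stacked-bar exports of HeLP decompositions (plotting convenience only)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def stacked_help_bars(help_table: pd.DataFrame, path, by: str = "index_condition"):
    """Stacked bars of HeLP contributions per index disorder (or age band).

    `help_table` is the help_results.csv schema; one bar per value of `by`,
    one layer per reported bucket.  Requires matplotlib (optional extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = help_table[help_table["age_band"] == "overall"] if by == "index_condition" else help_table
    pivot = df.pivot_table(
        index=by, columns="bucket", values="contribution", aggfunc="sum", fill_value=0.0
    )
    ax = pivot.plot(kind="bar", stacked=True, figsize=(10, 6))
    ax.set_ylabel("HeLP contribution")
    ax.set_xlabel(by.replace("_", " "))
    fig = ax.get_figure()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
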