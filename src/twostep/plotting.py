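"""Summary figures for stay/switch behaviour."""

from __future__ import annotations

import pandas as pd


def plot_stay_probabilities(table: pd.DataFrame, ax=None):
    """Grouped bar chart of the 2x2 stay-probability table.

    ``table`` is the output of
    :func:`twostep.pipeline.stay_probability_summary` (rows rewarded /
    unrewarded, columns common / rare). Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = [0, 1]
    width = 0.35
    ax.bar(
        [i - width / 2 for i in x],
        table["common"].to_numpy(),
        width,
        label="common",
        color="#4878d0",
    )
    ax.bar(
        [i + width / 2 for i in x],
        table["rare"].to_numpy(),
        width,
        label="rare",
        color="#ee854a",
    )
    ax.set_xticks(x, ["rewarded", "unrewarded"])
    ax.set_ylabel("stay probability")
    ax.set_ylim(0, 1)
    ax.legend(title="transition", frameon=False)
    return ax
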