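"""Quick-look figures: behaviour curves, index distributions, timecourses."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_behaviour", "plot_ci_histogram", "plot_index_timecourse"]


def plot_behaviour(log_frame, ax=None):
    """First-choice / correct-trial rates and reward across test blocks."""
    import matplotlib.pyplot as plt

    tests = log_frame[log_frame["phase"] == "test"]
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tests["iteration"], 100 * tests["first_choice_rate"], label="first choice")
    ax.plot(tests["iteration"], 100 * tests["correct_rate"], label="both choices")
    ax.axhline(98, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("iteration")
    ax.set_ylabel("correct rate (%)")
    ax.legend()
    return ax


def plot_ci_histogram(table, ax=None, bins=20):
    """Category-index distribution split by neuron class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = np.linspace(-1, 1, bins + 1)
    for cls, color in (("stimulus-neuron", "tab:blue"), ("category-neuron", "tab:red")):
        vals = table[table["class"] == cls]["CI"].dropna()
        ax.hist(vals, bins=edges, alpha=0.6, color=color, label=cls)
    ax.set_xlabel("category index")
    ax.set_ylabel("neurons")
    ax.legend()
    return ax


def plot_index_timecourse(timecourse, index="mean_CI", period="first_stimulus", ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = timecourse[timecourse["period"] == period]
    for cls, color in (("category-neuron", "tab:red"), ("stimulus-neuron", "tab:blue")):
        rows = sub[sub["class"] == cls]
        ax.plot(rows["iteration"], rows[index], marker="o", color=color, label=cls)
    ax.set_xlabel("iteration")
    ax.set_ylabel(index)
    ax.legend()
    return ax
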