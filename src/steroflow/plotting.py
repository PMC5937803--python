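"""Static figure export: per-place mean lines with variance bands."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["plot_trace"]

_COLOURS = {
    "testosterone": "tab:blue",
    "3α-diol": "tab:red",
    "androstenedione": "tab:green",
}


def plot_trace(
    summary: pd.DataFrame,
    places: Sequence[str],
    stage_boundaries: Sequence[int] = (20, 50),
    path: str | Path | None = None,
    ax=None,
):
    """Plot mean token flow per place with a mean±variance band.

    *summary* is the long-format table from :func:`steroflow.engine.summarize`
    (columns place, block, mean, variance).  Vertical markers at the stage
    boundaries separate the progenitor, immature and adult windows.  Returns
    the matplotlib Axes; writes a figure file when *path* is given.
    """
    import matplotlib.pyplot as plt

    known = set(summary["place"].unique())
    unknown = [p for p in places if p not in known]
    if unknown:
        raise KeyError(f"unknown places {unknown}; summary covers {sorted(known)}")

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for place in places:
        rows = summary[summary["place"] == place].sort_values("block")
        colour = _COLOURS.get(place)
        (line,) = ax.plot(rows["block"], rows["mean"], label=place, color=colour)
        ax.fill_between(
            rows["block"],
            rows["mean"] - rows["variance"],
            rows["mean"] + rows["variance"],
            alpha=0.25,
            color=line.get_color(),
        )
    for boundary in stage_boundaries:
        ax.axvline(boundary, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("time block")
    ax.set_ylabel("tokens")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
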