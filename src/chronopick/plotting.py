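"""A minimal plotting helper (untested decoration)."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .curve_io import CurveSet, Selection


def plot_selection(curves: CurveSet, selection: Optional[Selection] = None,
                   sampled: Optional[np.ndarray] = None, path: Optional[str] = None):
    """Plot the input curves, optional density samples, and selected times."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    t = curves.grid.times
    if sampled is not None:
        for row in np.atleast_2d(sampled):
            ax.plot(t, row, color="0.8", lw=0.6, zorder=1)
    for row in curves.values:
        ax.plot(t, row, color="C3", lw=1.2, zorder=2)
    if selection is not None:
        for i in selection.indices0:
            ax.axvline(t[i], color="C0", ls="--", lw=1.0, zorder=0)
    ax.set_xlabel("time")
    ax.set_ylabel("value")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
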