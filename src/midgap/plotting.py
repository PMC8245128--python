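"""Plot helpers for midline profiles and gap overlays."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .gapcall import GapCall, length_normalize
from .linescan import IntensityTrace

__all__ = ["plot_profiles", "plot_trace_with_gaps"]


def plot_profiles(
    traces: Sequence[IntensityTrace],
    channel: str,
    layer: str = "normalized",
    n_out: int = 100,
    ax=None,
    **plot_kw,
):
    """Overlay length-normalized single-channel profiles from many embryos.

    Each trace is resampled onto ``n_out`` points spanning anterior (0)
    to posterior (1) of its midline.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for trace in traces:
        values = getattr(trace, layer)
        if values is None:
            raise ValueError(f"trace has no {layer!r} layer")
        j = trace.channel_index(channel)
        frac, prof = length_normalize(values[:, j], trace.positions_um, n_out=n_out)
        ax.plot(frac, prof, **plot_kw)
    ax.set_xlabel("fraction of midline length (anterior to posterior)")
    ax.set_ylabel(f"{channel} {layer} intensity")
    return ax


def plot_trace_with_gaps(
    trace: IntensityTrace,
    gaps: Sequence[GapCall],
    thresholds: dict | None = None,
    ax=None,
):
    """Normalized two-channel profile with called gaps shaded."""
    import matplotlib.pyplot as plt

    if trace.normalized is None:
        raise ValueError("normalize the trace first")
    if ax is None:
        _, ax = plt.subplots()
    x = trace.positions_um
    for j, name in enumerate(trace.channel_names):
        ax.plot(x, trace.normalized[:, j], label=name)
        if thresholds and name in thresholds:
            ax.axhline(thresholds[name], ls="--", lw=0.8, color=f"C{j}")
    for gap in gaps:
        ax.axvspan(
            x[gap.start_idx], x[min(gap.end_idx, len(x)) - 1], alpha=0.2, color="grey"
        )
    ax.set_xlabel("position along midline (μm)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax
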