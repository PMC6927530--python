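"""Overlay plots of spatial expression profiles.

Layout follows the field's convention for dorsoventral expression readouts:
active-nucleus density on the x axis, EW position (0 = ventral, 100 = dorsal)
on the y axis, one panel per nuclear-cycle window, with the width call drawn
as a dashed span.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_profiles"]


def plot_profiles(
    profiles: pd.DataFrame,
    widths: pd.DataFrame | None,
    path: str | Path,
) -> Path:
    """Render per-window KDE profiles (tidy frame: window, grid_ew, density).

    ``widths`` (tidy: window, left, right, ventral_boundary), when given,
    adds the width span and ventral-boundary marker per panel.
    """
    windows = profiles["window"].drop_duplicates().tolist()
    fig, axes = plt.subplots(
        1, max(len(windows), 1), figsize=(2.2 * max(len(windows), 1), 4.0),
        sharey=True, squeeze=False,
    )
    by_width = widths.set_index("window") if widths is not None else None
    for ax, window in zip(axes[0], windows):
        sel = profiles[profiles["window"] == window]
        ax.plot(sel["density"], sel["grid_ew"], color="crimson", lw=1.5)
        if by_width is not None and window in by_width.index:
            row = by_width.loc[window]
            ax.axhspan(row["left"], row["right"], color="crimson", alpha=0.12)
            ax.axhline(row["ventral_boundary"], color="gray", ls="--", lw=0.8)
        ax.set_title(window, fontsize=9)
        ax.set_xlabel("density")
    axes[0][0].set_ylabel("EW position (0 = ventral)")
    axes[0][0].set_ylim(0, 100)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
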