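"""Temporal readouts: active-nucleus counts per nuclear-cycle window,
transcription-initiation times, and window-to-window change.

An *active nucleus* is a nucleus owning at least one detected dot in a frame.
Counts are averaged over all frames in each ~10-min window per embryo, then
across embryos (mean and SEM). Windows with no frames are reported as missing
rather than zero, so pooling embryos imaged over different developmental
spans does not bias cross-embryo means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .movie_io import UNASSIGNED, CycleWindow
from .segmentation import Dot

__all__ = [
    "dots_to_frame",
    "count_active",
    "aggregate_traces",
    "call_initiation",
    "earliest_window",
    "window_change",
    "match_nuclei",
]


def dots_to_frame(dots: Sequence[Dot]) -> pd.DataFrame:
    """Tidy per-dot table (frame, nucleus, y, x, pixel_count, size_metric, ew)."""
    return pd.DataFrame(
        {
            "frame": [d.frame for d in dots],
            "nucleus": [d.nucleus for d in dots],
            "y": [d.centroid[0] for d in dots],
            "x": [d.centroid[1] for d in dots],
            "pixel_count": [d.pixel_count for d in dots],
            "size_metric": [d.size_metric for d in dots],
            "ew": [d.ew if d.ew is not None else np.nan for d in dots],
        }
    )


def count_active(
    dots: pd.DataFrame,
    windows: Sequence[CycleWindow],
    n_frames: int,
    frame_counts: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Per-window mean active-nucleus count for one embryo.

    The per-frame count is the number of distinct nuclei owning >= 1 dot
    (frames within a window but with no dots count as zero). ``frame_counts``
    overrides per-frame counts for frames quantified outside the dot table
    (e.g. the per-slice early-cycle mode). Returns a tidy frame with columns
    window, mean_active, n_frames.
    """
    per_frame = np.zeros(n_frames, dtype=float)
    if len(dots):
        counted = dots.groupby("frame")["nucleus"].nunique()
        per_frame[counted.index.to_numpy()] = counted.to_numpy()
    if frame_counts:
        for t, c in frame_counts.items():
            per_frame[t] = c
    rows = []
    for w in windows:
        frames = [t for t in w.frames if 0 <= t < n_frames]
        if not frames:
            continue  # missing window: absent, not zero
        rows.append(
            {
                "window": w.label,
                "mean_active": float(np.mean(per_frame[frames])),
                "n_frames": len(frames),
            }
        )
    return pd.DataFrame(rows, columns=["window", "mean_active", "n_frames"])


def aggregate_traces(traces: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cross-embryo mean and SEM per window from per-embryo traces.

    SEM = sd / sqrt(n); NaN for windows observed in fewer than two embryos.
    Window order follows first appearance across embryos.
    """
    pooled = pd.concat(
        [t.assign(embryo=i) for i, t in enumerate(traces)], ignore_index=True
    )
    order = pooled["window"].drop_duplicates().tolist()
    rows = []
    for window in order:
        vals = pooled.loc[pooled["window"] == window, "mean_active"].to_numpy()
        rows.append(
            {
                "window": window,
                "mean_active": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) >= 2 else np.nan,
                "n_embryos": len(vals),
            }
        )
    return pd.DataFrame(rows)


def call_initiation(dots: pd.DataFrame, window_labels: Sequence[str]) -> pd.DataFrame:
    """First frame with a detected dot, per nucleus that is ever active.

    Initiation time is the first frame at which a dot was detected for that
    nucleus; the window label of that frame is attached. Never-active nuclei
    yield no call.
    """
    if not len(dots):
        return pd.DataFrame(columns=["nucleus", "first_frame", "window"])
    firsts = dots.groupby("nucleus")["frame"].min().reset_index()
    firsts.columns = ["nucleus", "first_frame"]
    firsts["window"] = [window_labels[t] for t in firsts["first_frame"]]
    return firsts.sort_values("nucleus").reset_index(drop=True)


def earliest_window(
    initiation: pd.DataFrame, window_order: Sequence[str]
) -> str | None:
    """The earliest nuclear-cycle window containing >= 1 initiation call."""
    seen = set(initiation["window"]) - {UNASSIGNED}
    for label in window_order:
        if label in seen:
            return label
    return None


def window_change(trace: pd.DataFrame, w1: str, w2: str) -> float:
    """Signed relative change (mean(w2) - mean(w1)) / mean(w1).

    NaN (with a warning) when mean(w1) is zero; raises if a window is absent.
    """
    by = trace.set_index("window")["mean_active"]
    for w in (w1, w2):
        if w not in by.index:
            raise KeyError(f"window {w!r} not present in trace")
    m1, m2 = float(by[w1]), float(by[w2])
    if m1 == 0:
        warnings.warn(f"window_change undefined: mean({w1!r}) is zero")
        return float("nan")
    return (m2 - m1) / m1


def match_nuclei(
    centroids_a: Mapping[int, tuple[float, float]],
    centroids_b: Mapping[int, tuple[float, float]],
    max_radius: float = 10.0,
) -> dict[int, int]:
    """Greedy nearest-centroid matching of nucleus identities across frames.

    Pairs are assigned in order of increasing distance; pairs farther apart
    than ``max_radius`` pixels are left unmatched. Returns {label_b: label_a}.
    """
    pairs = sorted(
        (float(np.hypot(ca[0] - cb[0], ca[1] - cb[1])), a, b)
        for a, ca in centroids_a.items()
        for b, cb in centroids_b.items()
    )
    used_a: set[int] = set()
    mapping: dict[int, int] = {}
    for dist, a, b in pairs:
        if dist > max_radius:
            break
        if a in used_a or b in mapping:
            continue
        mapping[b] = a
        used_a.add(a)
    return mapping
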