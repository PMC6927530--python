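"""Movie stacks, maximum-intensity projection, and nuclear-cycle windowing.

A movie is a five-dimensional intensity array indexed (t, z, channel, y, x)
with named channel roles: ``MCP`` (the nascent-transcript channel, MCP-GFP
bound to MS2 stem-loops) and ``NUP`` (the nuclear-envelope channel, Nup-RFP).
Frames are partitioned into nuclear-cycle windows (nc9 ... nc14c) by explicit,
configured frame ranges; cycle boundaries are inputs, not detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "MovieStack",
    "Projection",
    "CycleWindow",
    "NC_LABELS",
    "UNASSIGNED",
    "load_movie",
    "save_movie",
    "max_project",
    "assign_windows",
    "windows_from_counts",
]

#: Canonical nuclear-cycle window labels, in developmental order. nc14 is
#: subdivided into three ~10-min windows a/b/c.
NC_LABELS = ("nc9", "nc10", "nc11", "nc12", "nc13", "nc14a", "nc14b", "nc14c")

UNASSIGNED = "unassigned"

_ROLES = ("MCP", "NUP")


@dataclass
class MovieStack:
    """Raw intensities indexed (t, z, channel, y, x) plus channel roles."""

    data: np.ndarray
    channel_map: dict[str, int]
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(f"expected (t,z,c,y,x) data, got ndim={self.data.ndim}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        for role in _ROLES:
            if role not in self.channel_map:
                raise ValueError(f"channel_map is missing required role {role!r}")
        n_c = self.data.shape[2]
        for role, idx in self.channel_map.items():
            if not 0 <= idx < n_c:
                raise ValueError(
                    f"channel_map[{role!r}]={idx} out of range for {n_c} channel(s)"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """(t, z, y, x) intensities for one channel role."""
        return self.data[:, :, self.channel_map[role]]


@dataclass
class Projection:
    """Maximum-intensity projection: intensities indexed (t, channel, y, x)."""

    data: np.ndarray
    channel_map: dict[str, int]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected (t,c,y,x) data, got ndim={self.data.ndim}")

    def channel(self, role: str) -> np.ndarray:
        return self.data[:, self.channel_map[role]]


def max_project(stack: MovieStack) -> Projection:
    """Collapse z by the per-pixel maximum, per time point and channel."""
    return Projection(stack.data.max(axis=1), dict(stack.channel_map))


@dataclass(frozen=True)
class CycleWindow:
    """One nuclear-cycle time window: a 0-based half-open frame range.

    ``per_slice`` marks early windows (nc9/nc10, before nuclei finish
    migrating to the embryo periphery) where dot detection runs on individual
    z-slices and the per-time-point count is the maximum over slices.
    """

    label: str
    start: int
    stop: int
    per_slice: bool = False

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"window {self.label!r}: empty range [{self.start}, {self.stop})")

    @property
    def frames(self) -> range:
        return range(self.start, self.stop)


def windows_from_counts(
    counts: Mapping[str, int], per_slice_labels: Sequence[str] = ("nc9", "nc10")
) -> list[CycleWindow]:
    """Build consecutive windows from an ordered {label: n_frames} mapping."""
    windows = []
    start = 0
    for label, n in counts.items():
        windows.append(
            CycleWindow(label, start, start + int(n), per_slice=label in per_slice_labels)
        )
        start += int(n)
    return windows


def assign_windows(n_frames: int, windows: Sequence[CycleWindow]) -> list[str]:
    """Total frame -> window-label map; frames outside all windows are
    labeled ``unassigned`` (and excluded from per-window averages downstream).
    """
    ordered = sorted(windows, key=lambda w: w.start)
    for w in ordered:
        if w.start < 0 or w.stop > n_frames:
            raise ValueError(
                f"window {w.label!r} range [{w.start}, {w.stop}) outside [0, {n_frames})"
            )
    for a, b in zip(ordered, ordered[1:]):
        if a.stop > b.start:
            raise ValueError(f"windows {a.label!r} and {b.label!r} overlap")
    labels = [UNASSIGNED] * n_frames
    for w in ordered:
        for t in w.frames:
            labels[t] = w.label
    return labels


def save_movie(stack: MovieStack, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF with (t,z,c,y,x) axes tagged."""
    tifffile.imwrite(
        str(path),
        np.ascontiguousarray(stack.data),
        metadata={"axes": "TZCYX"},
    )


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand a tifffile array to (T, Z, C, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("Q", "T")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"cannot resolve image axes {axes!r}")
    # tifffile may report extra unit-length dims; squeeze anything unknown.
    keep = []
    for i, ax in enumerate(axes):
        if ax in "TZCYX":
            keep.append((ax, i))
        elif data.shape[i] == 1:
            continue
        else:
            raise ValueError(f"unsupported non-singleton axis {ax!r} in {axes!r}")
    data = data.transpose([i for _, i in keep]).reshape(
        [data.shape[i] for _, i in keep]
    )
    present = [ax for ax, _ in keep]
    order = [present.index(ax) for ax in "TZCYX" if ax in present]
    data = data.transpose(order)
    for pos, ax in enumerate("TZCYX"):
        if ax not in present:
            data = np.expand_dims(data, pos)
    return data


def load_movie(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> MovieStack:
    """Read a multi-page TIFF and normalize its axes to (t, z, c, y, x).

    A missing z dimension is treated as a single plane; a missing t dimension
    as a single time point. Raises if a required channel role is absent.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
    data = _normalize_axes(np.asarray(data), axes)
    return MovieStack(
        data.astype(np.float32, copy=False),
        dict(channel_map),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )
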