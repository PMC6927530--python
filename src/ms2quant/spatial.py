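"""Spatial readouts along the dorsoventral axis.

Dot positions are reduced to their EW (embryo width) component, a relative
0-100 coordinate between the ventral and dorsal extreme boundary points
(anterior-posterior coordinates are discarded). Per time point the package
computes a histogram with 4-pixel bins, a Gaussian kernel density estimate
with robust-Silverman bandwidth, the expression-domain width at a fraction
(default 0.30) of the KDE curve maximum, and the ventral boundary — the
ventral-most position where the profile drops below that threshold,
approximating where a ventral repressor (e.g. Snail) bounds the domain.
Replicate embryos differing in lateral mounting rotation are aligned by a
cross-correlation EW shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segmentation import EmbryoGeometry

__all__ = [
    "WidthPolicy",
    "WidthCall",
    "ExpressionProfile",
    "to_ew",
    "ew_histogram",
    "silverman_bandwidth",
    "kde_profile",
    "call_width",
    "call_ventral_boundary",
    "align_replicates",
]

EW_GRID_STEP = 0.25


@dataclass
class WidthPolicy:
    """Width-call parameters.

    ``th_fraction``: fraction of the KDE curve's own maximum (per time point)
    at which crossings are read. ``bandwidth_floor``: minimum Gaussian-kernel
    bandwidth in EW units, applied when Silverman's rule degenerates (few or
    identical positions). ``grid_step``: KDE evaluation grid spacing.
    """

    th_fraction: float = 0.30
    bandwidth_floor: float = 2.0
    grid_step: float = EW_GRID_STEP

    def __post_init__(self) -> None:
        if not 0 < self.th_fraction < 1:
            raise ValueError("th_fraction must be in (0, 1)")
        if self.bandwidth_floor <= 0:
            raise ValueError("bandwidth_floor must be > 0")


@dataclass(frozen=True)
class WidthCall:
    """Outermost threshold crossings of the KDE curve, in EW units."""

    left: float
    right: float

    @property
    def width(self) -> float:
        return self.right - self.left


@dataclass
class ExpressionProfile:
    """One time point's spatial expression readout along the EW axis."""

    positions: np.ndarray                # dot EW positions
    grid: np.ndarray                     # regular EW grid
    density: np.ndarray                  # KDE on the grid (integrates to 1)
    bandwidth: float
    histogram: tuple[np.ndarray, np.ndarray] | None = None   # (counts, edges)
    width_call: WidthCall | None = None
    ventral_boundary: float | None = None
    shift: float = 0.0                   # applied EW offset (replicate alignment)
    flags: list[str] = field(default_factory=list)


def to_ew(dots, geometry: EmbryoGeometry):
    """Attach EW positions to dots (list of Dot or tidy DataFrame with y, x)."""
    if isinstance(dots, pd.DataFrame):
        out = dots.copy()
        if len(out):
            out["ew"] = geometry.ew_of(out[["y", "x"]].to_numpy())
        return out
    for d in dots:
        d.ew = float(geometry.ew_of(np.array([d.centroid]))[0])
    return dots


def ew_histogram(
    ew_positions: np.ndarray,
    geometry: EmbryoGeometry | None = None,
    bin_pixels: int = 4,
    dv_extent_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of dot EW positions using bins of ``bin_pixels`` pixels.

    Bin edges are defined in pixel units along the DV axis and expressed in
    EW units. Each dot falls in exactly one bin via its single-pixel
    geometric-center coordinate.
    """
    if dv_extent_px is None:
        if geometry is None:
            raise ValueError("need geometry or dv_extent_px")
        dv_extent_px = geometry.dv_extent_px
    bin_ew = 100.0 * bin_pixels / dv_extent_px
    edges = np.arange(0.0, 100.0 + bin_ew, bin_ew)
    if edges[-1] < 100.0:
        edges = np.append(edges, edges[-1] + bin_ew)
    counts, edges = np.histogram(np.asarray(ew_positions, dtype=float), bins=edges)
    return counts, edges


def silverman_bandwidth(
    positions: np.ndarray, floor: float = WidthPolicy.bandwidth_floor
) -> float:
    """Robust Silverman plug-in bandwidth: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Degenerate samples (n < 2, zero spread) fall back to ``floor``; the floor
    is also a lower bound otherwise.
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n < 2:
        return float(floor)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        return float(floor)
    return float(max(0.9 * spread * n ** (-1 / 5), floor))


def kde_profile(ew_positions: np.ndarray, policy: WidthPolicy | None = None) -> ExpressionProfile:
    """Gaussian-mixture KDE of dot EW positions on a fixed 0-100 grid.

    One Gaussian kernel per position, bandwidth by the robust Silverman rule
    (with floor). The density is normalized over the real line, so it
    integrates to 1 (kernels near 0/100 may put small mass outside the grid).
    """
    policy = policy or WidthPolicy()
    x = np.asarray(ew_positions, dtype=float)
    if len(x) == 0:
        raise ValueError("no positions: cannot fit a density")
    h = silverman_bandwidth(x, policy.bandwidth_floor)
    grid = np.arange(0.0, 100.0 + policy.grid_step / 2, policy.grid_step)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))
    return ExpressionProfile(positions=x, grid=grid, density=density, bandwidth=h)


def _interp_crossing(grid, density, i_below, i_above, threshold) -> float:
    """EW position where the density crosses ``threshold`` between two
    adjacent grid points (linear interpolation)."""
    d0, d1 = density[i_below], density[i_above]
    if d1 == d0:
        return float(grid[i_above])
    frac = (threshold - d0) / (d1 - d0)
    return float(grid[i_below] + frac * (grid[i_above] - grid[i_below]))


def call_width(profile: ExpressionProfile, policy: WidthPolicy | None = None) -> WidthCall:
    """Width of the expression domain at ``th_fraction`` of the curve maximum.

    Crossings are the outermost positions where the density reaches the
    threshold, refined by linear interpolation between bracketing grid
    points; multi-modal profiles use the outermost crossings (flagged).
    """
    policy = policy or WidthPolicy()
    grid, density = profile.grid, profile.density
    threshold = policy.th_fraction * float(density.max())
    above = np.flatnonzero(density >= threshold)
    i0, i1 = int(above[0]), int(above[-1])
    if np.any(density[i0 : i1 + 1] < threshold):
        profile.flags.append("multimodal: outermost crossings used")
    left = (_interp_crossing(grid, density, i0 - 1, i0, threshold)
            if i0 > 0 else float(grid[0]))
    if i0 == 0:
        profile.flags.append("left crossing at grid edge")
    right = (_interp_crossing(grid, density, i1 + 1, i1, threshold)
             if i1 < len(grid) - 1 else float(grid[-1]))
    if i1 == len(grid) - 1:
        profile.flags.append("right crossing at grid edge")
    call = WidthCall(left, right)
    profile.width_call = call
    return call


def call_ventral_boundary(
    profile: ExpressionProfile, policy: WidthPolicy | None = None
) -> float:
    """Ventral-most EW position where the profile falls below threshold,
    moving ventrally (toward EW 0) from the curve peak.

    Equals the width call's left crossing for unimodal profiles. A profile
    still above threshold at EW 0 yields 0 and is flagged.
    """
    policy = policy or WidthPolicy()
    grid, density = profile.grid, profile.density
    threshold = policy.th_fraction * float(density.max())
    i = int(np.argmax(density))
    while i > 0 and density[i - 1] >= threshold:
        i -= 1
    if i == 0:
        profile.flags.append("profile above threshold down to EW 0")
        boundary = float(grid[0])
    else:
        boundary = _interp_crossing(grid, density, i - 1, i, threshold)
    profile.ventral_boundary = boundary
    return boundary


def _shifted(density: np.ndarray, grid: np.ndarray, shift: float) -> np.ndarray:
    """Evaluate the profile translated by ``shift`` EW units on the same grid."""
    return np.interp(grid - shift, grid, density, left=0.0, right=0.0)


def align_replicates(
    profiles: list[ExpressionProfile], max_shift: float = 15.0
) -> tuple[list[ExpressionProfile], list[float]]:
    """Align replicate profiles to the first one by an EW shift.

    For each profile the shift in [-max_shift, +max_shift] (grid-step
    resolution, ties broken toward zero) maximizing the cross-correlation
    with the reference density is applied. Corrects for differences in
    lateral mounting rotation between embryos.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to align")
    ref = profiles[0]
    step = float(ref.grid[1] - ref.grid[0])
    candidates = np.arange(-max_shift, max_shift + step / 2, step)
    candidates = candidates[np.argsort(np.abs(candidates), kind="stable")]
    out_profiles: list[ExpressionProfile] = [ref]
    shifts: list[float] = [0.0]
    for prof in profiles[1:]:
        if len(prof.grid) != len(ref.grid) or not np.allclose(prof.grid, ref.grid):
            raise ValueError("profiles must share the same EW grid")
        scores = [float(np.dot(ref.density, _shifted(prof.density, prof.grid, s)))
                  for s in candidates]
        best = float(candidates[int(np.argmax(scores))])
        shifted = replace(
            prof,
            positions=prof.positions + best,
            density=_shifted(prof.density, prof.grid, best),
            shift=prof.shift + best,
            flags=list(prof.flags),
        )
        out_profiles.append(shifted)
        shifts.append(best)
    return out_profiles, shifts
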