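"""Embryo geometry, nuclear segmentation, and nascent-dot detection.

The detection chain mirrors a standard MS2-MCP quantification recipe:
Gaussian smoothing (sigma 0.55) of the max-projected channels; a background
threshold (BTH) at a fraction (default 0.30) of maximum intensity in the MCP
channel; 4-connected clustering of suprathreshold pixels; a minimum cluster
size of 4 pixels for a callable dot; and exclusion of dots falling outside
Nup-labeled nuclei. Dot size is reported in 4-pixel units
(``size_metric = pixel_count / 4``), a proxy for the instantaneous
transcription rate (more nascent transcripts -> larger dot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.morphology import closing, disk
from skimage.segmentation import watershed

__all__ = [
    "EmbryoGeometry",
    "NucleiLabels",
    "Dot",
    "ThresholdPolicy",
    "smooth",
    "estimate_geometry",
    "segment_nuclei",
    "detect_dots",
    "window_dot_size",
    "dot_size_summary",
]


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundary handling."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndi.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


@dataclass
class EmbryoGeometry:
    """Embryo outline plus the two extreme points defining the EW axis.

    EW (embryo width) is a relative 0-100 coordinate along the dorsoventral
    axis: 0 at the ventral extreme, 100 at the dorsal extreme.
    """

    boundary: np.ndarray                      # (n, 2) closed polygon, (y, x)
    ventral_extreme: tuple[float, float]      # (y, x)
    dorsal_extreme: tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.ventral_extreme, dtype=float)
        d = np.asarray(self.dorsal_extreme, dtype=float)
        if np.allclose(v, d):
            raise ValueError("ventral and dorsal extremes coincide")

    def ew_of(self, points: np.ndarray, clip: bool = True) -> np.ndarray:
        """Map (y, x) points to EW via projection onto the ventral->dorsal axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = np.asarray(self.ventral_extreme, dtype=float)
        d = np.asarray(self.dorsal_extreme, dtype=float)
        axis = d - v
        ew = 100.0 * ((pts - v) @ axis) / (axis @ axis)
        if clip:
            n_out = int(np.sum((ew < 0) | (ew > 100)))
            if n_out:
                warnings.warn(f"{n_out} position(s) clipped to the [0, 100] EW range")
            ew = np.clip(ew, 0.0, 100.0)
        return ew if np.asarray(points).ndim > 1 else ew

    @property
    def dv_extent_px(self) -> float:
        """Pixel length of the ventral->dorsal axis (for 4-px histogram bins)."""
        v = np.asarray(self.ventral_extreme, dtype=float)
        d = np.asarray(self.dorsal_extreme, dtype=float)
        return float(np.linalg.norm(d - v))


def _snap_to_boundary(point, boundary: np.ndarray) -> tuple[float, float]:
    i = int(np.argmin(np.linalg.norm(boundary - np.asarray(point, dtype=float), axis=1)))
    return (float(boundary[i, 0]), float(boundary[i, 1]))


def estimate_geometry(
    nup_frame: np.ndarray,
    manual_extremes: tuple[tuple[float, float], tuple[float, float]] | None = None,
    dv_axis: Literal["y", "x"] = "y",
    ventral_side: Literal["high", "low"] = "high",
    boundary_sigma: float = 2.0,
    closing_radius: int = 8,
    contour_sigma: float = 5.0,
) -> EmbryoGeometry:
    """Estimate the embryo outline from the nuclear-envelope channel.

    The peripheral monolayer of nuclei is blurred into a continuous band,
    thresholded (Otsu), morphologically closed and hole-filled; the boundary
    is the contour of the largest resulting region, smoothed along its arc
    (``contour_sigma``, in boundary points) since an embryo outline is smooth
    at embryo scale while individual nuclei add pixel-scale scallops. Manual
    ventral/dorsal extremes, when given, are snapped to the boundary;
    otherwise the extremes default to the boundary points of extremal
    coordinate along the image axis designated as dorsoventral
    (``ventral_side`` picks which end of that axis is ventral; 'high' =
    larger pixel coordinate).
    """
    sm = smooth(nup_frame, boundary_sigma)
    if sm.max() <= 0 or np.ptp(sm) == 0:
        raise ValueError("blank frame: no embryo-scale region found")
    mask = sm > threshold_otsu(sm)
    if not mask.any():
        raise ValueError("no above-background region found")
    mask = closing(mask, disk(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    lbl = cc_label(mask)
    largest = np.argmax(np.bincount(lbl.ravel())[1:]) + 1
    mask = lbl == largest
    contours = find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len)
    if contour_sigma > 0 and len(boundary) > 10:
        pts = boundary[:-1] if np.allclose(boundary[0], boundary[-1]) else boundary
        pts = np.column_stack(
            [ndi.gaussian_filter1d(pts[:, i], contour_sigma, mode="wrap") for i in (0, 1)]
        )
        boundary = np.vstack([pts, pts[:1]])

    ax = 0 if dv_axis == "y" else 1
    if manual_extremes is not None:
        ventral = _snap_to_boundary(manual_extremes[0], boundary)
        dorsal = _snap_to_boundary(manual_extremes[1], boundary)
    else:
        hi = boundary[np.argmax(boundary[:, ax])]
        lo = boundary[np.argmin(boundary[:, ax])]
        ventral, dorsal = ((tuple(hi), tuple(lo)) if ventral_side == "high"
                           else (tuple(lo), tuple(hi)))
    return EmbryoGeometry(boundary, ventral, dorsal)


@dataclass
class NucleiLabels:
    """Per-frame labeled nuclear mask (0 = background; k > 0 = nucleus
    interior including envelope) plus centroids per label."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]]

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)

    def label_at(self, point) -> int:
        y = int(round(float(point[0])))
        x = int(round(float(point[1])))
        ny, nx = self.labels.shape
        if not (0 <= y < ny and 0 <= x < nx):
            return 0
        return int(self.labels[y, x])


def segment_nuclei(
    nup_frame: np.ndarray,
    geometry: EmbryoGeometry | None = None,
    sigma: float = 0.55,
    min_area: int = 20,
    split_min_distance: int = 5,
) -> NucleiLabels:
    """Segment ring-shaped nuclear envelopes into filled, labeled nuclei.

    Rings are closed by hole filling so that a dot inside a nucleus tests as
    inside; touching nuclei are split by watershed seeded from local maxima
    of the filled mask's distance transform; regions whose centroid falls
    outside the embryo boundary are discarded.
    """
    sm = smooth(nup_frame, sigma)
    if np.ptp(sm) == 0:
        return NucleiLabels(np.zeros(sm.shape, dtype=np.int32), {})
    mask = sm > threshold_otsu(sm)
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=split_min_distance, labels=cc_label(mask),
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    lbl = watershed(-distance, markers, mask=mask)

    embryo_mask = None
    if geometry is not None:
        from skimage.draw import polygon2mask

        embryo_mask = ndi.binary_dilation(
            polygon2mask(sm.shape, geometry.boundary), iterations=2
        )

    out = np.zeros(mask.shape, dtype=np.int32)
    centroids: dict[int, tuple[float, float]] = {}
    next_id = 1
    for region in regionprops(lbl):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        if embryo_mask is not None and not embryo_mask[int(round(cy)), int(round(cx))]:
            continue
        out[lbl == region.label] = next_id
        centroids[next_id] = (float(cy), float(cx))
        next_id += 1
    return NucleiLabels(out, centroids)


@dataclass
class Dot:
    """One segmented nascent-transcription dot (a 4-connected pixel cluster)."""

    frame: int
    pixels: np.ndarray                 # (n, 2) int (y, x)
    centroid: tuple[float, float]      # geometric center of the pixel cluster
    nucleus: int
    peak: float
    ew: float | None = None

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def size_metric(self) -> float:
        """Dot size in 4-pixel units: pixel_count / 4."""
        return self.pixel_count / 4.0


@dataclass
class ThresholdPolicy:
    """Detection parameters; every run logs the realized absolute threshold."""

    sigma: float = 0.55
    bth_fraction: float = 0.30
    max_scope: Literal["frame", "movie"] = "frame"
    min_pixels: int = 4
    membership: Literal["centroid", "majority"] = "centroid"

    def __post_init__(self) -> None:
        if not 0 < self.bth_fraction < 1:
            raise ValueError("bth_fraction must be in (0, 1)")


def detect_dots(
    mcp_frame: np.ndarray,
    policy: ThresholdPolicy,
    nuclei: NucleiLabels,
    frame_index: int = 0,
    movie_max: float | None = None,
    presmoothed: bool = False,
) -> list[Dot]:
    """Detect at most one dot per nucleus by fraction-of-max thresholding.

    Threshold = ``bth_fraction`` x maximum smoothed intensity (frame-scoped by
    default; pass ``movie_max`` with ``max_scope='movie'`` for a movie-wide
    reference). Suprathreshold pixels are clustered with 4-connectivity;
    clusters below ``min_pixels`` are dropped; clusters outside every nucleus
    are excluded (membership tested at the cluster's geometric center by
    default). If several clusters share one nucleus the largest survives
    (ties: brightest peak, then smallest centroid coordinates).
    """
    sm = mcp_frame if presmoothed else smooth(mcp_frame, policy.sigma)
    if policy.max_scope == "movie":
        if movie_max is None:
            raise ValueError("movie_max required with max_scope='movie'")
        reference = movie_max
    else:
        reference = float(sm.max())
    if reference <= 0:
        warnings.warn(f"frame {frame_index}: all-zero image, no dots detected")
        return []
    threshold = policy.bth_fraction * reference

    mask = sm > threshold
    lbl = cc_label(mask, connectivity=1)
    best: dict[int, Dot] = {}
    for region in regionprops(lbl, intensity_image=sm):
        if region.area < policy.min_pixels:
            continue
        pixels = region.coords
        centroid = (float(region.centroid[0]), float(region.centroid[1]))
        if policy.membership == "centroid":
            nucleus = nuclei.label_at(centroid)
        else:
            labels_under = nuclei.labels[pixels[:, 0], pixels[:, 1]]
            inside = labels_under[labels_under > 0]
            nucleus = (int(np.bincount(inside).argmax())
                       if len(inside) > len(labels_under) / 2 else 0)
        if nucleus == 0:
            continue
        dot = Dot(frame_index, pixels, centroid, nucleus,
                  peak=float(region.intensity_max))
        prev = best.get(nucleus)
        if prev is None or (
            (dot.pixel_count, dot.peak, (-centroid[0], -centroid[1]))
            > (prev.pixel_count, prev.peak, (-prev.centroid[0], -prev.centroid[1]))
        ):
            best[nucleus] = dot
    return sorted(best.values(), key=lambda d: (d.centroid[0], d.centroid[1]))


def window_dot_size(dots_by_frame: Mapping[int, Sequence[Dot]]) -> float:
    """Window-level dot size: per-frame mean of ``pixel_count / 4``, then the
    mean over frames that contain at least one dot. Raises if no dots at all."""
    frame_means = [
        float(np.mean([d.size_metric for d in dots]))
        for dots in dots_by_frame.values()
        if len(dots)
    ]
    if not frame_means:
        raise ValueError("no dots in window")
    return float(np.mean(frame_means))


def dot_size_summary(per_embryo_values: Sequence[float]) -> tuple[float, float]:
    """Cross-embryo mean and SEM (sd / sqrt(n)); SEM is NaN for n < 2."""
    vals = np.asarray(per_embryo_values, dtype=float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else float("nan")
    return mean, sem
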