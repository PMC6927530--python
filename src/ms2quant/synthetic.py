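"""Synthetic two-channel embryo movies with exact ground truth.

The generator emulates the geometric and statistical structure the imaging
pipeline assumes for a laterally mounted syncytial-blastoderm embryo:

* an elliptical embryo outline in a 512x512 field, with the dorsoventral (DV)
  axis along image y (ventral at the bottom of the image, EW 0);
* a peripheral monolayer of ring-shaped nuclear envelopes (the NUP channel),
  placed deterministically along the ellipse so the ring outer edges lie on
  the embryo boundary;
* at most one compact, bright sub-nuclear dot per active nucleus per frame
  (the MCP channel), with known integer pixel areas, plus uniform background
  and additive noise;
* a ventrolaterally restricted stripe of active nuclei whose count and EW
  extent are set per nuclear-cycle window, emulating the rise from nc10 to
  nc13 and the decline through nc14a-c.

Dots are rendered as truncated Gaussian intensity profiles on an explicitly
chosen pixel set, so true per-dot pixel counts are known integers. With the
default (easy-mode) settings every dot survives fraction-of-max thresholding
at 0.30 after smoothing while the background does not, making exact recovery
a fair end-to-end test; ``hard_mode`` dims a fraction of dots and raises the
noise to probe threshold sensitivity.

Nuclei are static: nuclear movement and division dynamics are out of scope,
and all downstream statistics are per-frame or per-window.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .movie_io import MovieStack, load_movie, save_movie

__all__ = [
    "WindowActivity",
    "SimulationConfig",
    "GroundTruth",
    "generate_movie",
    "write_fixture",
    "load_fixture",
    "default_config",
]


@dataclass(frozen=True)
class WindowActivity:
    """Activity model for one nuclear-cycle window: how many nuclei transcribe
    and the EW interval (ventral, dorsal bounds in 0-100 units) they occupy."""

    n_active: int
    ew_interval: tuple[float, float] = (20.0, 60.0)

    def __post_init__(self) -> None:
        v, d = self.ew_interval
        if not 0 <= v < d <= 100:
            raise ValueError(f"invalid EW activity interval [{v}, {d}]")
        if self.n_active < 0:
            raise ValueError("n_active must be >= 0")


def _default_windows() -> dict[str, int]:
    # ~10 frames per ~10-min window at ~60 s per scan, nc9 through nc14c.
    return {lbl: 10 for lbl in
            ("nc9", "nc10", "nc11", "nc12", "nc13", "nc14a", "nc14b", "nc14c")}


def _default_activity() -> dict[str, WindowActivity]:
    # Wild-type-like trajectory: onset at nc10 with a handful of nuclei,
    # rising to a nc13 peak, declining through nc14a-c.
    counts = {"nc9": 0, "nc10": 4, "nc11": 8, "nc12": 14,
              "nc13": 22, "nc14a": 18, "nc14b": 14, "nc14c": 10}
    return {lbl: WindowActivity(n) for lbl, n in counts.items()}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic embryo; the seed fixes every random draw."""

    shape: tuple[int, int] = (512, 512)          # (ny, nx) pixels
    n_z: int = 3                                  # z-planes per time point
    window_frames: dict[str, int] = field(default_factory=_default_windows)
    ellipse_center: tuple[float, float] | None = None   # (cy, cx); default image center
    semi_axes: tuple[float, float] = (170.0, 230.0)      # (b along y=DV, a along x=AP)
    n_nuclei: int = 90
    nucleus_radius: float = 5.5
    ring_thickness: float = 2.0
    activity: dict[str, WindowActivity] = field(default_factory=_default_activity)
    dot_area_range: tuple[int, int] = (6, 10)     # inclusive, pixels per dot
    dot_peak_range: tuple[float, float] = (0.85, 1.0)
    background_mean: float = 0.10
    noise_sd: float = 0.015
    hard_mode: bool = False
    seed: int = 0

    def center(self) -> tuple[float, float]:
        if self.ellipse_center is not None:
            return self.ellipse_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    @property
    def n_frames(self) -> int:
        return sum(self.window_frames.values())

    def frame_window(self, t: int) -> str:
        start = 0
        for lbl, n in self.window_frames.items():
            if start <= t < start + n:
                return lbl
            start += n
        raise IndexError(t)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activity"] = {
            lbl: {"n_active": a.n_active, "ew_interval": list(a.ew_interval)}
            for lbl, a in self.activity.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "activity" in d:
            d["activity"] = {
                lbl: WindowActivity(int(a["n_active"]), tuple(a["ew_interval"]))
                for lbl, a in d["activity"].items()
            }
        for key in ("shape", "semi_axes", "dot_area_range", "dot_peak_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("ellipse_center") is not None:
            d["ellipse_center"] = tuple(d["ellipse_center"])
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions with a caller-chosen seed."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


@dataclass
class NucleusTruth:
    """Static truth for one nucleus: center (y, x) and EW position."""

    nucleus_id: int
    center: tuple[float, float]
    ew: float


@dataclass
class FrameTruth:
    """Per-frame truth: which nuclei are active and their dot pixel sets."""

    frame: int
    window: str
    active: list[int]
    dot_pixels: dict[int, list[tuple[int, int]]]   # nucleus id -> (y, x) pixels
    dot_centers: dict[int, tuple[float, float]]

    @property
    def n_active(self) -> int:
        return len(self.active)


@dataclass
class GroundTruth:
    """Complete generator bookkeeping for a synthetic movie."""

    nuclei: list[NucleusTruth]
    frames: list[FrameTruth]
    windows: dict[str, dict]   # label -> {n_active, ew_interval, mean_dot_area, frames}
    ventral_extreme: tuple[float, float]
    dorsal_extreme: tuple[float, float]

    def frame_count(self, t: int) -> int:
        return self.frames[t].n_active

    def window_count(self, label: str) -> int:
        return int(self.windows[label]["n_active"])

    def to_dict(self) -> dict:
        return {
            "nuclei": [
                {"id": n.nucleus_id, "center": list(n.center), "ew": n.ew}
                for n in self.nuclei
            ],
            "frames": [
                {
                    "frame": f.frame,
                    "window": f.window,
                    "active": list(f.active),
                    "dot_pixels": {str(k): [list(p) for p in v] for k, v in f.dot_pixels.items()},
                    "dot_centers": {str(k): list(v) for k, v in f.dot_centers.items()},
                }
                for f in self.frames
            ],
            "windows": self.windows,
            "ventral_extreme": list(self.ventral_extreme),
            "dorsal_extreme": list(self.dorsal_extreme),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            nuclei=[
                NucleusTruth(int(n["id"]), tuple(n["center"]), float(n["ew"]))
                for n in d["nuclei"]
            ],
            frames=[
                FrameTruth(
                    int(f["frame"]),
                    f["window"],
                    [int(i) for i in f["active"]],
                    {int(k): [tuple(p) for p in v] for k, v in f["dot_pixels"].items()},
                    {int(k): tuple(v) for k, v in f["dot_centers"].items()},
                )
                for f in d["frames"]
            ],
            windows={k: dict(v) for k, v in d["windows"].items()},
            ventral_extreme=tuple(d["ventral_extreme"]),
            dorsal_extreme=tuple(d["dorsal_extreme"]),
        )


def _place_nuclei(cfg: SimulationConfig) -> list[NucleusTruth]:
    """Deterministic, evenly spaced placement along the embryo periphery.

    Centers lie on the ellipse shrunk by one nucleus radius, so ring outer
    edges sit on the embryo boundary (the pipeline's boundary estimate is
    validated against the true ellipse).
    """
    cy, cx = cfg.center()
    b, a = cfg.semi_axes
    R = cfg.nucleus_radius
    if a - R <= 0 or b - R <= 0:
        raise ValueError("nuclei do not fit inside the embryo ellipse")
    thetas = 2 * np.pi * (np.arange(cfg.n_nuclei) + 0.35) / cfg.n_nuclei
    ys = cy + (b - R) * np.sin(thetas)
    xs = cx + (a - R) * np.cos(thetas)
    # reject configurations where neighboring nuclei would merge
    pts = np.column_stack([ys, xs])
    gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    if gaps.min() < 2 * R:
        raise ValueError(
            f"nuclei overlap: minimum center spacing {gaps.min():.1f} px "
            f"< nucleus diameter {2 * R:.1f} px; reduce n_nuclei or radius"
        )
    y_v, y_d = cy + b, cy - b   # ventral at image bottom (larger y)
    return [
        NucleusTruth(k + 1, (float(ys[k]), float(xs[k])),
                     float(100.0 * (y_v - ys[k]) / (y_v - y_d)))
        for k in range(cfg.n_nuclei)
    ]


def _render_nup(cfg: SimulationConfig, nuclei: Sequence[NucleusTruth],
                rng: np.random.Generator) -> np.ndarray:
    ny, nx = cfg.shape
    img = np.zeros((ny, nx), dtype=np.float32)
    R, w = cfg.nucleus_radius, cfg.ring_thickness
    yy, xx = np.mgrid[0:ny, 0:nx]
    for nuc in nuclei:
        cy, cx = nuc.center
        y0, y1 = int(max(0, cy - R - 2)), int(min(ny, cy + R + 3))
        x0, x1 = int(max(0, cx - R - 2)), int(min(nx, cx + R + 3))
        d = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        ring = (d <= R) & (d >= R - w)
        level = rng.uniform(0.9, 1.0)
        patch = img[y0:y1, x0:x1]
        patch[ring] = np.maximum(patch[ring], level)
    return img


def _dot_pixel_set(center: tuple[float, float], area: int,
                   shape: tuple[int, int]) -> np.ndarray:
    """The ``area`` in-bounds pixels nearest the dot center: a compact,
    4-connected cluster with an exactly known integer pixel count."""
    cy, cx = center
    r = int(np.ceil(np.sqrt(area / np.pi))) + 2
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inb = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    d = np.hypot(yy - cy, xx - cx)
    d[~inb] = np.inf
    flat = np.argsort(d, axis=None, kind="stable")[:area]
    picked = np.column_stack(np.unravel_index(flat, d.shape))
    picked[:, 0] += y0
    picked[:, 1] += x0
    return picked


def _render_dot(img: np.ndarray, pixels: np.ndarray, center: tuple[float, float],
                peak: float) -> None:
    """Truncated-Gaussian profile on the chosen pixel set: the outermost set
    pixels stay near 0.6 x peak so the whole set survives thresholding at
    0.3 of frame max after light smoothing, while the off-set halo does not."""
    d = np.hypot(pixels[:, 0] - center[0], pixels[:, 1] - center[1])
    dmax = max(d.max(), 1e-6)
    sigma = dmax / np.sqrt(2 * np.log(1 / 0.60))
    vals = peak * np.exp(-(d ** 2) / (2 * sigma ** 2))
    img[pixels[:, 0], pixels[:, 1]] = np.maximum(img[pixels[:, 0], pixels[:, 1]], vals)


def generate_movie(cfg: SimulationConfig) -> tuple[MovieStack, GroundTruth]:
    """Render the movie and its exact ground truth. Deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.shape
    nuclei = _place_nuclei(cfg)
    cy, cx = cfg.center()
    b, _ = cfg.semi_axes

    for lbl in cfg.activity:
        if lbl not in cfg.window_frames:
            raise ValueError(f"activity given for unknown window {lbl!r}")

    nup = _render_nup(cfg, nuclei, rng)
    nup_noise = rng.normal(0.0, cfg.noise_sd / 2, size=(ny, nx)).astype(np.float32)
    nup = np.clip(nup + 0.05 + nup_noise, 0, None)

    ews = np.array([n.ew for n in nuclei])
    peak_lo, peak_hi = cfg.dot_peak_range
    if cfg.hard_mode:
        peak_lo = min(peak_lo, 0.65)
    area_lo, area_hi = cfg.dot_area_range
    noise_sd = cfg.noise_sd * (3.0 if cfg.hard_mode else 1.0)
    # hard mode: a dim subpopulation of dots whose smoothed peak can fall
    # below 0.3 x frame max — deliberately violating the easy-mode
    # signal-to-background guarantee so threshold sensitivity is testable
    dim_fraction = 0.10 if cfg.hard_mode else 0.0
    dim_range = (0.30, 0.45)

    # middle z-plane carries full dot intensity; neighbors are attenuated so
    # the max projection preserves every dot
    zc = (cfg.n_z - 1) / 2.0
    z_fac = np.exp(-((np.arange(cfg.n_z) - zc) ** 2) / 2.0).astype(np.float32)

    data = np.zeros((cfg.n_frames, cfg.n_z, 2, ny, nx), dtype=np.float32)
    frames: list[FrameTruth] = []
    windows: dict[str, dict] = {}

    t = 0
    jitter_r = max(cfg.nucleus_radius - cfg.ring_thickness - 2.5, 0.0)
    for lbl, n_frames_w in cfg.window_frames.items():
        act = cfg.activity.get(lbl, WindowActivity(0))
        v, d_hi = act.ew_interval
        eligible = [n.nucleus_id for n, e in zip(nuclei, ews) if v <= e <= d_hi]
        if act.n_active > len(eligible):
            raise ValueError(
                f"window {lbl!r}: {act.n_active} active nuclei requested but only "
                f"{len(eligible)} nuclei lie in EW [{v}, {d_hi}]"
            )
        active = sorted(rng.choice(eligible, size=act.n_active, replace=False).tolist()) \
            if act.n_active else []
        areas_seen: list[int] = []
        for _ in range(n_frames_w):
            mcp = np.clip(
                cfg.background_mean
                + rng.normal(0.0, noise_sd, size=(ny, nx)).astype(np.float32),
                0, 0.25,
            )
            dot_pixels: dict[int, list[tuple[int, int]]] = {}
            dot_centers: dict[int, tuple[float, float]] = {}
            dots_img = np.zeros((ny, nx), dtype=np.float32)
            for nid in active:
                nuc = nuclei[nid - 1]
                ang = rng.uniform(0, 2 * np.pi)
                rad = jitter_r * np.sqrt(rng.uniform())
                center = (nuc.center[0] + rad * np.sin(ang),
                          nuc.center[1] + rad * np.cos(ang))
                area = int(rng.integers(area_lo, area_hi + 1))
                pixels = _dot_pixel_set(center, area, cfg.shape)
                if dim_fraction and rng.uniform() < dim_fraction:
                    peak = rng.uniform(*dim_range)
                else:
                    peak = rng.uniform(peak_lo, peak_hi)
                _render_dot(dots_img, pixels, center, peak)
                dot_pixels[nid] = [tuple(int(v_) for v_ in p) for p in pixels]
                dot_centers[nid] = (float(center[0]), float(center[1]))
                areas_seen.append(area)
            for z in range(cfg.n_z):
                data[t, z, 0] = np.maximum(mcp, dots_img * z_fac[z])
                data[t, z, 1] = nup * (0.85 + 0.15 * z_fac[z])
            frames.append(FrameTruth(t, lbl, list(active), dot_pixels, dot_centers))
            t += 1
        windows[lbl] = {
            "n_active": act.n_active,
            "ew_interval": list(act.ew_interval),
            "mean_dot_area": float(np.mean(areas_seen)) if areas_seen else None,
            "frames": [frames[-n_frames_w].frame, frames[-1].frame + 1],
        }

    truth = GroundTruth(
        nuclei=nuclei,
        frames=frames,
        windows=windows,
        ventral_extreme=(float(cy + b), float(cx)),
        dorsal_extreme=(float(cy - b), float(cx)),
    )
    stack = MovieStack(data, {"MCP": 0, "NUP": 1}, pixel_size_um=None,
                       frame_interval_s=60.0)
    return stack, truth


def write_fixture(movie: MovieStack, truth: GroundTruth, cfg: SimulationConfig,
                  directory: str | Path) -> Path:
    """Write movie TIFF + ground-truth JSON + generating config to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_movie(movie, directory / "movie.tif")
    (directory / "truth.json").write_text(json.dumps(truth.to_dict()))
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return directory


def load_fixture(directory: str | Path) -> tuple[MovieStack, GroundTruth, SimulationConfig]:
    """Read back a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(f"fixture {directory} has no config.yaml")
    cfg = SimulationConfig.from_dict(yaml.safe_load(cfg_path.read_text()))
    truth = GroundTruth.from_dict(json.loads((directory / "truth.json").read_text()))
    movie = load_movie(directory / "movie.tif", {"MCP": 0, "NUP": 1})
    return movie, truth, cfg
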