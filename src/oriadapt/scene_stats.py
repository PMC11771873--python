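"""Temporal orientation statistics of gaze-centered video.

Pipeline: crop a 6x6-degree patch around gaze in every frame, estimate local
orientation at multiple scales with first-order steerable (Gaussian
derivative) filters, compute sliding-window circular statistics of the
orientation history at every position, and accumulate the distribution of the
next frame's orientation relative to the history mean, conditioned on the
history's circular variance.

Orientation is pi-periodic, so all circular statistics are computed on
doubled angles and reported differences are halved back (axial statistics).
A history window whose doubled-angle mean resultant length is R has circular
variance V = 1 - R: V = 0 for a perfectly stable orientation history and
V ~ 1 for a uniform one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

PATCH_DEG_DEFAULT = 6.0
WINDOW_FRAMES_DEFAULT = 72
N_HIST_BINS = 37  # odd, so one bin is centered at zero difference


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """Grayscale video with gaze metadata.

    frames: (T, H, W) float array in [0, 1]; gaze: (T, 2) pixel coordinates
    (x, y) of the gaze center per frame.
    """

    frames: np.ndarray
    frame_rate: float
    deg_per_pixel: float
    gaze: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.gaze.shape != (self.frames.shape[0], 2):
            raise ValueError("gaze must be (T, 2)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_tiff(self, tiff_path, sidecar_path) -> None:
        """Write a multi-page 8-bit TIFF plus the JSON sidecar."""
        import tifffile

        data = np.clip(self.frames * 255.0, 0, 255).astype(np.uint8)
        tifffile.imwrite(tiff_path, data)
        sidecar = {
            "frame_rate_hz": self.frame_rate,
            "deg_per_pixel": self.deg_per_pixel,
            "gaze_xy": self.gaze.tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def from_tiff(cls, tiff_path, sidecar_path) -> "FrameStack":
        import tifffile

        frames = tifffile.imread(tiff_path).astype(float) / 255.0
        if frames.ndim == 2:
            frames = frames[None]
        with open(sidecar_path) as fh:
            side = json.load(fh)
        return cls(frames=frames, frame_rate=side["frame_rate_hz"],
                   deg_per_pixel=side["deg_per_pixel"],
                   gaze=np.asarray(side["gaze_xy"], dtype=float))


@dataclass
class LevelField:
    """Per-frame orientation estimates at one pyramid level.

    orientation: (T, n, n) radians in [-pi/2, pi/2); magnitude: filter
    response energy; valid: False where the response magnitude vanishes and
    orientation is undefined.
    """

    level: int
    orientation: np.ndarray
    magnitude: np.ndarray
    valid: np.ndarray


@dataclass
class OrientationField:
    """Orientation estimates for all requested pyramid levels."""

    levels: dict  # level -> LevelField

    def __getitem__(self, level: int) -> LevelField:
        return self.levels[level]


@dataclass
class SlidingStats:
    """Sliding circular mean / variance per level.

    For level arrays of T frames and window w, entry j corresponds to the
    window covering frames [j, j + w - 1]; its "next frame" is j + w.
    """

    window_frames: int
    mean: dict      # level -> (T - w + 1, n, n) axial mean, radians
    variance: dict  # level -> (T - w + 1, n, n) circular variance in [0, 1]


@dataclass
class ConditionalHistogram:
    """Histogram of next-frame orientation minus history mean, pooled."""

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    variance_band: tuple
    n_samples: int
    empty: bool = False
    meta: dict = dc_field(default_factory=dict)

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def gaze_patch(stack: FrameStack, patch_deg: float = PATCH_DEG_DEFAULT):
    """Per-frame square crops centered at gaze, clamped at frame borders.

    Returns (patches, clamped) where patches is (T, p, p) and clamped flags
    frames whose crop had to be shifted to stay inside the frame.
    """
    p = int(round(patch_deg / stack.deg_per_pixel))
    T, H, W = stack.frames.shape
    if p > H or p > W:
        raise ConfigurationError(
            f"patch of {p} px exceeds frame size {H}x{W}"
        )
    patches = np.empty((T, p, p), dtype=float)
    clamped = np.zeros(T, dtype=bool)
    for t in range(T):
        gx, gy = stack.gaze[t]
        x0 = int(round(gx)) - p // 2
        y0 = int(round(gy)) - p // 2
        cx0, cy0 = np.clip(x0, 0, W - p), np.clip(y0, 0, H - p)
        clamped[t] = (cx0 != x0) or (cy0 != y0)
        patches[t] = stack.frames[t, cy0:cy0 + p, cx0:cx0 + p]
    return patches, clamped


def _level_orientation(images: np.ndarray, sigma: float = 1.5):
    """First-order steerable orientation estimate for a stack of images.

    The response of a first-derivative filter steered to angle alpha is
    cos(alpha) Gx + sin(alpha) Gy, so the angle of maximal absolute response
    follows in closed form from the two basis responses: alpha* =
    atan2(Gy, Gx). The local structure (contour) orientation is alpha* +
    pi/2, reported pi-periodic.
    """
    bp = images - ndimage.gaussian_filter(images, sigma=(0, 2 * sigma, 2 * sigma))
    gx = ndimage.gaussian_filter(bp, sigma=(0, sigma, sigma), order=(0, 0, 1))
    gy = ndimage.gaussian_filter(bp, sigma=(0, sigma, sigma), order=(0, 1, 0))
    mag = np.hypot(gx, gy)
    ori = np.arctan2(gy, gx) + np.pi / 2.0
    ori = np.mod(ori + np.pi / 2.0, np.pi) - np.pi / 2.0
    valid = mag > 1e-12 * max(float(mag.max()), 1e-300)
    return ori, mag, valid


def orientation_field(patches: np.ndarray, levels=(2, 3, 4)) -> OrientationField:
    """Multi-scale orientation estimates.

    Level L operates at 1 / 2^(L-1) of the patch resolution (each level halves
    the resolution of the previous one); estimates use band-passed Gaussian
    derivative filters at each level.
    """
    patches = np.asarray(patches, dtype=float)
    out = {}
    current = patches
    current_level = 1
    for level in sorted(levels):
        while current_level < level:
            current = ndimage.gaussian_filter(current, sigma=(0, 1.0, 1.0))[:, ::2, ::2]
            current_level += 1
        ori, mag, valid = _level_orientation(current)
        out[level] = LevelField(level=level, orientation=ori, magnitude=mag, valid=valid)
    return OrientationField(levels=out)


def sliding_circular_stats(
    field: OrientationField, window_frames: int = WINDOW_FRAMES_DEFAULT
) -> SlidingStats:
    """Sliding axial mean and circular variance of the orientation history.

    Computed on doubled angles via cumulative sums: mean = arg of the mean
    resultant vector halved, variance = 1 - mean resultant length.
    """
    means, variances = {}, {}
    for level, lf in field.levels.items():
        T = lf.orientation.shape[0]
        if T < window_frames + 1:
            raise ConfigurationError(
                f"need at least window_frames + 1 = {window_frames + 1} frames, got {T}"
            )
        c = np.cos(2.0 * lf.orientation)
        s = np.sin(2.0 * lf.orientation)
        cc = np.concatenate([np.zeros_like(c[:1]), np.cumsum(c, axis=0)])
        ss = np.concatenate([np.zeros_like(s[:1]), np.cumsum(s, axis=0)])
        w = window_frames
        mc = (cc[w:] - cc[:-w]) / w
        ms = (ss[w:] - ss[:-w]) / w
        R = np.hypot(mc, ms)
        means[level] = 0.5 * np.arctan2(ms, mc)
        variances[level] = np.clip(1.0 - R, 0.0, 1.0)
    return SlidingStats(window_frames=window_frames, mean=means, variance=variances)


def wrap_axial(x) -> np.ndarray:
    """Wrap a pi-periodic orientation difference to [-pi/2, pi/2)."""
    return np.mod(np.asarray(x) + np.pi / 2.0, np.pi) - np.pi / 2.0


def next_frame_conditional(
    field: OrientationField,
    stats: SlidingStats,
    variance_band: tuple,
    mag_threshold: float = 0.0,
) -> ConditionalHistogram:
    """Distribution of next-frame orientation relative to the history mean.

    Pools every (level, position, time) whose window circular variance falls
    inside ``variance_band``; the orientation one frame after the window's
    last frame is compared to the window's circular mean. Positions whose
    next-frame response magnitude falls below ``mag_threshold`` (quantile of
    the level's magnitudes, in [0, 1)) are excluded when the threshold is
    positive.
    """
    lo, hi = variance_band
    w = stats.window_frames
    edges = np.linspace(-90.0, 90.0, N_HIST_BINS + 1)
    counts = np.zeros(N_HIST_BINS)
    n_samples = 0
    for level, lf in field.levels.items():
        V = stats.variance[level]
        M = stats.mean[level]
        n_windows = V.shape[0] - 1  # last window has no next frame
        if n_windows <= 0:
            continue
        nxt = lf.orientation[w:]          # frame following window j is j + w
        nxt_valid = lf.valid[w:]
        sel = (V[:n_windows] >= lo) & (V[:n_windows] < hi) & nxt_valid[:n_windows]
        if mag_threshold > 0:
            thr = np.quantile(lf.magnitude, mag_threshold)
            sel &= lf.magnitude[w:][:n_windows] >= thr
        if not np.any(sel):
            continue
        diff = wrap_axial(nxt[:n_windows][sel] - M[:n_windows][sel])
        diff_deg = np.degrees(diff)
        diff_deg[diff_deg == -90.0] = 90.0  # bins cover (-90, 90]
        h, _ = np.histogram(diff_deg, bins=edges)
        counts += h
        n_samples += int(sel.sum())
    return ConditionalHistogram(
        bin_edges_deg=edges, counts=counts, variance_band=(lo, hi),
        n_samples=n_samples, empty=n_samples == 0,
        meta={"window_frames": w, "mag_threshold": mag_threshold,
              "levels": sorted(field.levels)},
    )
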