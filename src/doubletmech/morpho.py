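"""Junction- and image-level morphometrics.

Implements the quantities used to characterize junction dynamics and
protein organization: polyline length and straightness, angular
deviation over a time window, ROI-restricted Pearson colocalization,
normalized intensity line profiles, threshold-based particle analysis,
and two-channel junctional intensity ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "JunctionTrace",
    "RoiImagePair",
    "junction_length",
    "straightness",
    "angular_deviation",
    "pearson_roi",
    "intensity_profile",
    "analyze_particles",
    "junction_intensity_ratio",
]


@dataclass
class JunctionTrace:
    """Junction polylines over time: list of (time_min, (n, 2) µm points)."""

    frames: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for _, poly in self.frames:
            if np.asarray(poly).shape[0] < 2:
                raise ValueError("each polyline needs at least 2 points")


@dataclass
class RoiImagePair:
    """Two aligned intensity channels plus a region-of-interest mask."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a)
        b = np.asarray(self.channel_b)
        m = np.asarray(self.roi_mask, dtype=bool)
        if not (a.shape == b.shape == m.shape):
            raise ValueError("channels and ROI mask must share one shape")
        if not m.any():
            raise ValueError("ROI mask is empty")
        self.channel_a, self.channel_b, self.roi_mask = a, b, m


def junction_length(polyline: np.ndarray) -> float:
    """Accumulated (arc) length of a polyline in µm."""
    pts = np.asarray(polyline, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def straightness(polyline: np.ndarray) -> float:
    """Euclidean / accumulated length ratio, in (0, 1].

    1 for a perfectly straight junction; a closed loop returns 0 with a
    warning (the chord is degenerate).
    """
    pts = np.asarray(polyline, dtype=float)
    acc = junction_length(pts)
    if acc <= 0:
        raise ValueError("accumulated length must be > 0")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        warnings.warn("closed polyline: straightness undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return chord / acc


def _chord_angle(polyline: np.ndarray) -> float | None:
    pts = np.asarray(polyline, dtype=float)
    chord = pts[-1] - pts[0]
    if np.allclose(chord, 0.0):
        return None
    return float(np.degrees(np.arctan2(chord[1], chord[0])))


def _axial_difference(a: float, b: float) -> float:
    """Absolute difference of two axial angles, wrapped to [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def angular_deviation(
    trace: JunctionTrace, window_min: float, statistic: str = "mean"
) -> float:
    """Summary of chord-angle deviation from the initial junction axis.

    Per frame within ``window_min`` minutes of the first frame, the
    endpoint-chord angle is compared to the frame-0 chord angle; the
    axial (headless) difference is wrapped to [0°, 90°].  The default
    summary is the mean absolute deviation over the window
    (``statistic="max"`` for the maximum).  Frames with a degenerate
    chord are skipped with a warning.
    """
    t0 = trace.frames[0][0]
    angle0 = _chord_angle(trace.frames[0][1])
    if angle0 is None:
        raise ValueError("frame 0 chord is degenerate")
    devs = []
    for t, poly in trace.frames:
        if t - t0 > window_min:
            break
        ang = _chord_angle(poly)
        if ang is None:
            warnings.warn(f"degenerate chord at t={t} min: frame skipped",
                          stacklevel=2)
            continue
        devs.append(_axial_difference(ang, angle0))
    if len(devs) < 2:
        raise ValueError("need at least 2 frames within the window")
    if statistic == "mean":
        return float(np.mean(devs))
    if statistic == "max":
        return float(np.max(devs))
    raise ValueError("statistic must be 'mean' or 'max'")


def pearson_roi(pair: RoiImagePair) -> float | None:
    """Pearson correlation of the two channels over in-ROI pixels only.

    Returns ``None`` (undefined-result signal) when either channel has
    zero variance inside the ROI; requires at least 3 in-ROI pixels.
    """
    a = pair.channel_a[pair.roi_mask].astype(float)
    b = pair.channel_b[pair.roi_mask].astype(float)
    if a.size < 3:
        raise ValueError("need at least 3 in-ROI pixels")
    da, db = a - a.mean(), b - b.mean()
    va, vb = np.mean(da**2), np.mean(db**2)
    if va == 0.0 or vb == 0.0:
        return None
    return float(np.mean(da * db) / np.sqrt(va * vb))


class Profile(NamedTuple):
    positions: np.ndarray  # arc-length positions of the samples (µm)
    raw: np.ndarray
    normalized: np.ndarray
    normalization_skipped: bool


def intensity_profile(
    image: np.ndarray,
    line: np.ndarray,
    n_samples: int = 100,
    pixel_size: float = 1.0,
) -> Profile:
    """Bilinear line-scan profile, normalized to its maximum.

    Samples the image at ``n_samples`` equidistant arc-length positions
    along the polyline ``line`` (given in µm; converted to pixel
    coordinates with ``pixel_size``).  The normalized profile divides by
    the maximum sample, so the peak equals 1; an all-zero scan skips
    normalization and sets the flag.
    """
    pts = np.asarray(line, dtype=float) / pixel_size
    if pts.shape[0] < 2:
        raise ValueError("line needs at least 2 points")
    img = np.asarray(image, dtype=float)
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > img.shape[1] - 1
            or pts[:, 1].max() > img.shape[0] - 1):
        raise ValueError("line extends outside the image bounds")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, cum[-1], n_samples)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    raw = ndimage.map_coordinates(img, [y, x], order=1, mode="nearest")
    peak = raw.max()
    if peak <= 0:
        return Profile(s * pixel_size, raw, raw.copy(), True)
    return Profile(s * pixel_size, raw, raw / peak, False)


def analyze_particles(
    image: np.ndarray,
    threshold: float | str,
    min_area: float = 0.0,
    pixel_size: float = 1.0,
) -> tuple[int, list[float]]:
    """Count thresholded objects and report their areas in µm².

    Pixels strictly above ``threshold`` (absolute intensity, or
    ``"otsu"`` for an automatic threshold) are grouped into 8-connected
    components; components smaller than ``min_area`` µm² are discarded.
    An empty result is valid: a blank image yields ``(0, [])``.
    """
    img = np.asarray(image, dtype=float)
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return 0, []
        threshold = float(threshold_otsu(img))
    else:
        threshold = float(threshold)
        if img.size and not (img.min() <= threshold <= img.max()):
            raise ValueError("threshold outside the image intensity range")
    binary = img > threshold
    labels = measure.label(binary, connectivity=2)
    areas = [
        float(region.area) * pixel_size**2
        for region in measure.regionprops(labels)
    ]
    areas = sorted(a for a in areas if a >= min_area)
    return len(areas), areas


def junction_intensity_ratio(pair: RoiImagePair) -> float | None:
    """Ratio of the two channels' mean intensities within the ROI.

    mean(A) / mean(B) over in-ROI pixels; ``None`` (undefined-result
    signal) when the denominator is zero.
    """
    mean_a = float(pair.channel_a[pair.roi_mask].mean())
    mean_b = float(pair.channel_b[pair.roi_mask].mean())
    if mean_b == 0.0:
        return None
    return mean_a / mean_b
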