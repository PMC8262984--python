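"""Colony color segmentation and tube intensity profiles.

Congo-red colony images are segmented in HSB space: pixels whose hue (on
the 0-255 scale) falls in a red gate are red-eligible, and k-means with
k=3 splits pixels into red, brown and black/background bins.  Tube images
reduce to a per-row mean-intensity profile; pellicle formation is the
trapezoidal integral of the profile over a fixed pixel range.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skimage import color as skcolor

LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentationResult:
    red_pixels: int
    brown_pixels: int
    background_pixels: int

    @property
    def total(self) -> int:
        return self.red_pixels + self.brown_pixels + self.background_pixels

    @property
    def red_fraction(self) -> float:
        denom = self.red_pixels + self.brown_pixels
        if denom == 0:
            return 0.0
        return self.red_pixels / denom


@dataclass
class IntensityProfile:
    values: np.ndarray  # per-row mean intensity, top row first
    inverted: bool = False

    def __len__(self) -> int:
        return len(self.values)


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("an RGB image is required")
    rgb = image[..., :3].astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    return rgb


def segment_congo_red(
    image: np.ndarray,
    hue_low: float = 1.0,
    hue_high: float = 14.0,
    hue_scale: float = 255.0,
    value_floor: float = 0.15,
    seed: int = 0,
    n_restarts: int = 10,
) -> SegmentationResult:
    """Count red / brown / background pixels of a colony image.

    Hue thresholds are on a 0..``hue_scale`` hue axis (ImageJ-style 0-255
    by default).  k-means (k=3, fixed seed, ``n_restarts`` restarts) runs
    in HSB space; the lowest-brightness centroid is the background bin and
    a non-background cluster is called red only if its centroid hue sits
    inside the gate; red pixels must additionally pass the gate
    themselves.
    """
    from sklearn.cluster import KMeans

    rgb = _as_rgb_float(image)
    hsv = skcolor.rgb2hsv(rgb)
    pixels = hsv.reshape(-1, 3)
    hue = pixels[:, 0] * hue_scale
    in_gate = (hue >= hue_low) & (hue <= hue_high)

    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(pixels)
    centroids = km.cluster_centers_
    background_cluster = int(np.argmin(centroids[:, 2]))
    red_clusters = {
        k
        for k in range(3)
        if k != background_cluster
        and hue_low <= centroids[k, 0] * hue_scale <= hue_high
    }

    is_background = labels == background_cluster
    # guard: very dark pixels count as background even if clustered otherwise
    is_background |= pixels[:, 2] < value_floor
    is_red = np.isin(labels, list(red_clusters)) & in_gate & ~is_background
    red = int(is_red.sum())
    background = int(is_background.sum())
    brown = int(pixels.shape[0] - red - background)
    return SegmentationResult(red, brown, background)


def normalize_dye_uptake(
    red_fractions, wild_type_fractions
) -> np.ndarray:
    """Fold dye binding relative to the mean wild-type red fraction."""
    wt = np.asarray(wild_type_fractions, dtype=float)
    if wt.size == 0:
        raise ValueError("need >= 1 wild-type result")
    wt_mean = wt.mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean red fraction is zero")
    return np.asarray(red_fractions, dtype=float) / wt_mean


def vertical_profile(image: np.ndarray, invert: bool = False) -> IntensityProfile:
    """Per-row mean grayscale intensity (luma), top row = index 0.

    With ``invert`` the profile is (max - luma) so that dark stain reads
    as high signal.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = np.tensordot(image[..., :3].astype(float), LUMA, axes=([2], [0]))
    elif image.ndim == 2:
        gray = image.astype(float)
    else:
        raise ValueError("expected a 2-D gray or 3-D RGB image")
    maxval = 255.0 if np.asarray(image).max() > 1.0 else 1.0
    if invert:
        gray = maxval - gray
    return IntensityProfile(gray.mean(axis=1), inverted=invert)


def pellicle_score(
    profile: IntensityProfile,
    range_start: int = 2000,
    range_end: int = 2500,
) -> float:
    """Trapezoidal integral of the profile over [range_start, range_end].

    The range is clipped to the profile bounds with a warning.
    """
    if range_start >= range_end:
        raise ValueError("range_start must be < range_end")
    n = len(profile)
    lo, hi = range_start, range_end
    if lo < 0 or hi > n - 1:
        warnings.warn(
            f"pellicle range [{range_start}, {range_end}] clipped to profile "
            f"bounds [0, {n - 1}]"
        )
        lo, hi = max(lo, 0), min(hi, n - 1)
    if hi <= lo:
        return 0.0
    return float(np.trapezoid(profile.values[lo:hi + 1]))
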