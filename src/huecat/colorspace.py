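"""Circular hue arithmetic and training-band construction.

Hues are unitless fractions of the HSV hue circle, stored in ``[0, 1)``.
All arithmetic wraps modulo 1.  The spectrum under study is the set of
fully saturated, maximum-brightness colors (the edges of the RGB cube),
so HSV -> RGB conversion is only ever needed at S = V = 1 (and, for
dimmed backgrounds, at a reduced value channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "wrap_hue",
    "hue_to_rgb",
    "circular_distance",
    "circular_weighted_mean",
    "circular_median",
    "HueBand",
    "HueBandSet",
    "make_uniform_bands",
    "sample_hue_from_band",
    "bin_centers",
    "bin_index",
]


def wrap_hue(h):
    """Wrap hue(s) into [0, 1)."""
    return np.asarray(h, dtype=float) % 1.0


def hue_to_rgb(h, value: float = 1.0):
    """Convert hue(s) at full saturation to RGB in [0, 1].

    Parameters
    ----------
    h : float or array-like
        Hue fraction(s) in ``[0, 1)``.
    value : float
        HSV value (brightness) channel; saturation is fixed at 1.

    Returns
    -------
    ndarray
        ``(..., 3)`` float RGB.  For ``value = 1`` the result lies on the
        edges of the RGB cube: one channel is 1 and one is 0.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h >= 1):
        raise ValueError("hue must lie in [0, 1)")
    h6 = h * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    # S = 1 => p = 0, q = 1 - f, t = f
    r = np.choose(i, [np.ones_like(f), 1.0 - f, np.zeros_like(f),
                      np.zeros_like(f), f, np.ones_like(f)])
    g = np.choose(i, [f, np.ones_like(f), np.ones_like(f),
                      1.0 - f, np.zeros_like(f), np.zeros_like(f)])
    b = np.choose(i, [np.zeros_like(f), np.zeros_like(f), f,
                      np.ones_like(f), np.ones_like(f), 1.0 - f])
    return np.stack([r, g, b], axis=-1) * value


def rgb8(h, value: float = 1.0) -> np.ndarray:
    """8-bit RGB triple(s) for raster writing (round half up)."""
    return np.floor(hue_to_rgb(h, value) * 255.0 + 0.5).astype(np.uint8)


def circular_distance(a, b):
    """Shortest distance on the hue circle, in [0, 0.5]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 1.0
    return np.minimum(d, 1.0 - d)


def circular_weighted_mean(hues, weights=None) -> float:
    """Weighted circular mean: angle of the weighted resultant vector.

    Raises
    ------
    ValueError
        If no weight is positive or the resultant vector vanishes
        (the mean direction is undefined).
    """
    hues = np.asarray(hues, dtype=float)
    if weights is None:
        weights = np.ones_like(hues)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be nonnegative with at least one positive")
    ang = 2.0 * np.pi * hues
    x = float(np.sum(weights * np.cos(ang)))
    y = float(np.sum(weights * np.sin(ang)))
    if np.hypot(x, y) < 1e-12 * float(np.sum(weights)):
        raise ValueError("circular mean undefined: zero resultant vector")
    return float((np.arctan2(y, x) / (2.0 * np.pi)) % 1.0)


def circular_median(hues) -> float:
    """Circular median: the sample point minimizing total circular distance.

    Ties are broken toward the point whose hue fraction is smallest.
    """
    hues = wrap_hue(np.atleast_1d(hues))
    if hues.size == 0:
        raise ValueError("empty sample")
    cost = np.array([circular_distance(h, hues).sum() for h in hues])
    order = np.lexsort((hues, cost))
    return float(hues[order[0]])


@dataclass(frozen=True)
class HueBand:
    """A circular hue interval ``[center - half_width, center + half_width)``."""

    center: float
    half_width: float

    def __post_init__(self):
        if not 0 < self.half_width < 0.5:
            raise ValueError("half_width must lie in (0, 0.5)")
        object.__setattr__(self, "center", float(self.center) % 1.0)

    @property
    def width(self) -> float:
        return 2.0 * self.half_width

    def contains(self, h) -> np.ndarray:
        """Half-open circular containment test."""
        rel = (np.asarray(h, dtype=float) - (self.center - self.half_width)) % 1.0
        return rel < self.width

    def sample(self, rng: np.random.Generator, size=None):
        """Uniform draw(s) from the band (wrapped)."""
        u = rng.uniform(-self.half_width, self.half_width, size=size)
        return (self.center + u) % 1.0


@dataclass(frozen=True)
class HueBandSet:
    """K uniformly spaced training bands with a global circular shift.

    Band centers sit at ``shift + k/K``; the summed band widths equal
    ``total_width`` of the hue circle (default 0.2).
    """

    n_classes: int
    shift: float
    total_width: float = 0.2
    bands: tuple = field(init=False, repr=False)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 < self.total_width < 1:
            raise ValueError("total_width must lie in (0, 1)")
        object.__setattr__(self, "shift", float(self.shift) % 1.0)
        hw = self.total_width / (2.0 * self.n_classes)
        bands = tuple(
            HueBand((self.shift + k / self.n_classes) % 1.0, hw)
            for k in range(self.n_classes)
        )
        object.__setattr__(self, "bands", bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    def to_config(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "shift": self.shift,
            "total_width": self.total_width,
        }


def make_uniform_bands(n_classes: int, shift: float, total_width: float = 0.2) -> HueBandSet:
    """Construct the K shifted training bands (summed widths = ``total_width``)."""
    return HueBandSet(n_classes=n_classes, shift=shift, total_width=total_width)


def sample_hue_from_band(band: HueBand, rng: np.random.Generator, size=None):
    """Uniform hue draw(s) from a circular band."""
    return band.sample(rng, size=size)


def bin_centers(n_bins: int) -> np.ndarray:
    """Evaluation hues: centers of ``n_bins`` equal spectrum bins.

    Bin ``b`` covers ``[b/N, (b+1)/N)``; its center is ``(b + 0.5)/N``.
    """
    return (np.arange(n_bins) + 0.5) / n_bins


def bin_index(h, n_bins: int) -> np.ndarray:
    """Index of the spectrum bin containing hue(s) ``h``."""
    return np.floor(wrap_hue(h) * n_bins).astype(int) % n_bins
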