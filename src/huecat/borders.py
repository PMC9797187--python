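"""Border analytics on classification rows.

Given stacks of spectrum-evaluation rows (one per trained probe head),
this module finds the class-transition edges, accumulates them into a
transition count over the hue circle, detects peaks (the candidate
category borders), computes reciprocal-weighted category prototypes, and
quantifies categorical vs. continuous behavior through the circular
cross-correlation shift analysis, an exact/Monte-Carlo Fisher test and a
histogram-overlap statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter1d
from scipy.special import gammaln
from scipy.stats import random_table

from .colorspace import bin_centers, circular_weighted_mean, hue_to_rgb

__all__ = [
    "column_mode",
    "row_modes",
    "find_transitions",
    "TransitionCount",
    "accumulate_transition_counts",
    "BorderEstimate",
    "detect_peaks",
    "PrototypeSet",
    "compute_prototypes",
    "row_to_unit_circle",
    "optimal_circular_shift",
    "fold_lag",
    "ShiftHistogram",
    "shift_distribution",
    "FisherResult",
    "fisher_exact_table",
    "distribution_overlap",
]


def column_mode(column) -> int:
    """Most frequent label in a sample column; ties go to the lowest class index."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty column has no mode")
    return int(np.argmax(np.bincount(column)))


def row_modes(samples: np.ndarray) -> np.ndarray:
    """Per-column modes of an ``(n_bins, samples_per_bin)`` label grid."""
    samples = np.asarray(samples)
    return np.array([column_mode(samples[b]) for b in range(samples.shape[0])])


def find_transitions(mode_row) -> np.ndarray:
    """Circular bin-edge indices where the mode row changes class.

    Edge ``e`` separates bin ``e - 1`` from bin ``e``; edge 0 closes the
    circle.  A non-constant circular sequence always has >= 2 transitions.
    """
    row = np.asarray(mode_row)
    return np.nonzero(row != np.roll(row, 1))[0]


@dataclass
class TransitionCount:
    """Raw per-edge transition counts and their circular Gaussian smoothing."""

    raw: np.ndarray
    sigma: float = 1.5

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if np.any(self.raw < 0):
            raise ValueError("transition counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return int(self.raw.shape[0])

    @property
    def smoothed(self) -> np.ndarray:
        return gaussian_filter1d(self.raw.astype(float), self.sigma, mode="wrap")


def _as_mode_row(row) -> np.ndarray:
    return np.asarray(getattr(row, "mode_row", row))


def accumulate_transition_counts(rows, sigma: float = 1.5) -> TransitionCount:
    """Sum border transitions over a stack of rows."""
    mode_rows = [_as_mode_row(r) for r in rows]
    if not mode_rows:
        raise ValueError("no rows to accumulate")
    n = len(mode_rows[0])
    raw = np.zeros(n, dtype=int)
    for mr in mode_rows:
        if len(mr) != n:
            raise ValueError("rows have mixed bin counts")
        raw[find_transitions(mr)] += 1
    return TransitionCount(raw=raw, sigma=sigma)


@dataclass
class BorderEstimate:
    """Ordered circular border positions, as bin-edge hues."""

    positions: np.ndarray
    n_bins: int

    def __post_init__(self):
        self.positions = np.sort(np.asarray(self.positions, dtype=float) % 1.0)
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError("border positions must be pairwise distinct")

    @property
    def n_borders(self) -> int:
        return int(len(self.positions))

    @property
    def edge_indices(self) -> np.ndarray:
        return np.round(self.positions * self.n_bins).astype(int) % self.n_bins


def detect_peaks(
    tc: TransitionCount,
    min_separation: int = 5,
    prominence_frac: float = 0.10,
    use_smoothed: bool = False,
) -> BorderEstimate:
    """Circular local maxima of the transition count.

    Peaks must clear a minimum prominence (a fraction of the signal
    maximum) and a minimum inter-peak separation in bins.  A flat signal
    yields an empty estimate.
    """
    x = tc.smoothed if use_smoothed else tc.raw.astype(float)
    n = len(x)
    if np.ptp(x) == 0:
        return BorderEstimate(positions=np.empty(0), n_bins=n)
    tiled = np.tile(x, 3)
    peaks, _ = _signal.find_peaks(
        tiled, distance=min_separation, prominence=prominence_frac * x.max()
    )
    idx = np.unique(peaks[(peaks >= n) & (peaks < 2 * n)] - n)
    return BorderEstimate(positions=idx / n, n_bins=n)


@dataclass
class PrototypeSet:
    """Per-category border pair, prototype hue, and prototype RGB."""

    left: np.ndarray
    right: np.ndarray
    prototype: np.ndarray
    rgb: np.ndarray = field(init=False)

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.prototype = np.asarray(self.prototype, dtype=float)
        self.rgb = hue_to_rgb(self.prototype)

    def __len__(self) -> int:
        return len(self.prototype)


def compute_prototypes(borders: BorderEstimate, tc: TransitionCount) -> PrototypeSet:
    """Reciprocal-transition-weighted circular mean hue of each category.

    Each category spans two consecutive borders; member bins are weighted
    by ``1 / (raw_count + 1)`` so hues where borders rarely occur dominate.
    """
    if borders.n_borders < 2:
        raise ValueError("need at least 2 borders to form categories")
    n = tc.n_bins
    centers = bin_centers(n)
    pos = borders.positions
    lefts, rights, protos = [], [], []
    for i in range(len(pos)):
        left, right = pos[i], pos[(i + 1) % len(pos)]
        span = (right - left) % 1.0
        rel = (centers - left) % 1.0
        member = rel < span
        if not np.any(member):
            raise ValueError(f"category [{left}, {right}) contains no bins")
        w = 1.0 / (tc.raw[member] + 1.0)
        protos.append(circular_weighted_mean(centers[member], w))
        lefts.append(left)
        rights.append(right)
    return PrototypeSet(left=np.array(lefts), right=np.array(rights),
                        prototype=np.array(protos))


def row_to_unit_circle(mode_row, bands) -> tuple:
    """Replace each bin's class label by its band-center hue on the unit circle.

    Returns the two coordinate signals ``(x, y)`` with ``x^2 + y^2 = 1``.
    """
    row = _as_mode_row(mode_row)
    centers = bands.centers if hasattr(bands, "centers") else np.asarray(bands)
    if np.any(row < 0) or np.any(row >= len(centers)):
        raise ValueError("class label out of range for the band set")
    ang = 2.0 * np.pi * centers[row]
    return np.cos(ang), np.sin(ang)


def fold_lag(lag: float, period: float) -> int:
    """Fold a raw circular lag into the signed range around zero.

    The fold period is the (generally non-integer) band spacing in bins,
    ``n_bins / K``; folding by its integer rounding instead would corrupt
    lags far from zero whenever the spacing does not divide ``n_bins``.
    The folded real lag in ``[-P/2, P/2)`` (half-period mapped to +P/2)
    is rounded to whole bins.
    """
    s = lag - period * np.floor(lag / period + 0.5)
    if s <= -period / 2:
        s += period
    return int(np.rint(s))


def _circular_xcorr(ax, ay, bx, by) -> np.ndarray:
    """``c[l] = sum_i a[i] . b[i+l]`` over circular lags, via FFT."""
    n = len(ax)
    fa_x, fa_y = np.fft.rfft(ax), np.fft.rfft(ay)
    fb_x, fb_y = np.fft.rfft(bx), np.fft.rfft(by)
    return (np.fft.irfft(np.conj(fa_x) * fb_x, n)
            + np.fft.irfft(np.conj(fa_y) * fb_y, n))


def optimal_circular_shift(row_a, row_b, bands_a, bands_b=None) -> int:
    """Signed circular lag (in bins) maximizing the 2D cross-correlation.

    Rows are mapped to unit-circle coordinate signals first; the best raw
    lag is folded by the band period ``n_bins / K`` into the signed range
    around zero (about -P/2 .. P/2).  Positive shift means row B lags
    row A.  Ties are broken to the smallest ``|shift|``, then to the
    negative shift.
    """
    bands_b = bands_b if bands_b is not None else bands_a
    ax, ay = row_to_unit_circle(row_a, bands_a)
    bx, by = row_to_unit_circle(row_b, bands_b)
    if len(ax) != len(bx):
        raise ValueError("rows must share n_bins")
    k_a = len(bands_a.centers) if hasattr(bands_a, "centers") else len(bands_a)
    k_b = len(bands_b.centers) if hasattr(bands_b, "centers") else len(bands_b)
    if k_a != k_b:
        raise ValueError("rows must share the number of classes")
    n = len(ax)
    period = n / k_a  # band spacing in bins; non-integer in general
    c = _circular_xcorr(ax, ay, bx, by)
    best = c.max()
    candidates = np.nonzero(c >= best - 1e-9 * (abs(best) + 1.0))[0]
    folded = sorted((fold_lag(l, period) for l in candidates),
                    key=lambda s: (abs(s), s))
    return folded[0]


@dataclass
class ShiftHistogram:
    """Distribution of pairwise optimal shifts, folded to the band period.

    ``period`` is the band spacing in bins (``n_bins / K``, generally
    non-integer); folded integer shifts span ``-half .. half`` with
    ``half = round(period / 2)``.
    """

    period: float
    shifts: np.ndarray  # signed, one entry per unordered row pair

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=int)

    @property
    def half(self) -> int:
        return int(np.floor(self.period / 2 + 0.5))

    @property
    def support(self) -> np.ndarray:
        return np.arange(-self.half, self.half + 1)

    def signed_counts(self) -> np.ndarray:
        return np.bincount(self.shifts + self.half,
                           minlength=2 * self.half + 1)

    def abs_support(self) -> np.ndarray:
        return np.arange(self.half + 1)

    def abs_counts(self) -> np.ndarray:
        """Counts of positive shift distances (each unordered pair once)."""
        return np.bincount(np.abs(self.shifts), minlength=self.half + 1)

    def frac_within(self, k: int) -> float:
        return float(np.mean(np.abs(self.shifts) <= k))


def shift_distribution(rows, bands_per_row) -> ShiftHistogram:
    """Optimal circular shifts over all unordered row pairs.

    ``bands_per_row`` is either one band set shared by all rows or a
    sequence aligned with ``rows``.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    if hasattr(bands_per_row, "centers"):
        bands = [bands_per_row] * len(rows)
    else:
        bands = list(bands_per_row)
    ks = {len(b.centers) for b in bands}
    if len(ks) != 1:
        raise ValueError("all rows must share the number of classes")
    k = ks.pop()
    n = len(_as_mode_row(rows[0]))
    period = n / k
    coords = [row_to_unit_circle(r, b) for r, b in zip(rows, bands)]
    fx = [np.fft.rfft(x) for x, _ in coords]
    fy = [np.fft.rfft(y) for _, y in coords]
    shifts = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            c = (np.fft.irfft(np.conj(fx[i]) * fx[j], n)
                 + np.fft.irfft(np.conj(fy[i]) * fy[j], n))
            best = c.max()
            cand = np.nonzero(c >= best - 1e-9 * (abs(best) + 1.0))[0]
            folded = sorted((fold_lag(l, period) for l in cand),
                            key=lambda s: (abs(s), s))
            shifts.append(folded[0])
    return ShiftHistogram(period=period, shifts=np.array(shifts))


@dataclass
class FisherResult:
    p_value: float
    method: str  # "enumeration" | "monte-carlo"
    se: float = 0.0

    def __float__(self) -> float:
        return self.p_value


def _validate_counts(cols) -> np.ndarray:
    table = np.column_stack([np.asarray(c) for c in cols])
    if table.ndim != 2:
        raise ValueError("count columns must be one-dimensional")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        arr = np.asarray(table, dtype=float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        table = np.round(arr).astype(int)
    return table


def _table_stat(table: np.ndarray) -> float:
    # conditional probability of a table given margins is proportional to
    # exp(-sum lgamma(cell + 1)); larger stat <=> less probable table
    return float(np.sum(gammaln(np.asarray(table, dtype=float) + 1.0)))


def _enumerate_p(table: np.ndarray) -> float:
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = int(table.sum())
    log_const = (np.sum(gammaln(rows + 1.0)) + np.sum(gammaln(cols + 1.0))
                 - gammaln(n + 1.0))
    obs = _table_stat(table)
    tol = 1e-9
    r, c = table.shape
    total = 0.0

    def rec(row_idx: int, col_rem: np.ndarray, acc: float):
        nonlocal total
        if row_idx == r - 1:
            stat = acc + float(np.sum(gammaln(col_rem + 1.0)))
            if stat >= obs - tol:
                total += math.exp(log_const - stat)
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, rem: int, acc2: float, col_rem2: np.ndarray):
            if col_idx == c - 1:
                if rem <= col_rem2[col_idx]:
                    nxt = col_rem2.copy()
                    nxt[col_idx] -= rem
                    rec(row_idx + 1, nxt, acc2 + gammaln(rem + 1.0))
                return
            hi = min(rem, int(col_rem2[col_idx]))
            for v in range(hi + 1):
                nxt = col_rem2.copy()
                nxt[col_idx] -= v
                fill(col_idx + 1, rem - v, acc2 + gammaln(v + 1.0), nxt)

        fill(0, target, acc, col_rem)

    rec(0, cols.astype(float), 0.0)
    return min(total, 1.0)


def fisher_exact_table(
    counts_a,
    counts_b,
    counts_c=None,
    enumeration_cap: int = 200,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> FisherResult:
    """Fisher's exact test on an r x 2 (or r x 3) contingency table.

    The p-value is the probability, under fixed margins, of tables at
    most as probable as the observed one.  Full enumeration is used when
    the table total is within ``enumeration_cap``; otherwise a
    Monte-Carlo estimate over Patefield-sampled tables is returned with
    its standard error.
    """
    cols = [counts_a, counts_b] + ([counts_c] if counts_c is not None else [])
    table = _validate_counts(cols)
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")
    if n <= enumeration_cap:
        return FisherResult(p_value=_enumerate_p(table), method="enumeration")
    rng = rng if rng is not None else np.random.default_rng()
    rt = random_table(table.sum(axis=1), table.sum(axis=0), seed=rng)
    samples = rt.rvs(n_mc)
    stats = np.sum(gammaln(samples + 1.0), axis=(1, 2))
    obs = _table_stat(table)
    hits = np.count_nonzero(stats >= obs - 1e-9)
    p = hits / n_mc
    se = math.sqrt(max(p * (1 - p), 1.0 / n_mc) / n_mc)
    return FisherResult(p_value=p, method="monte-carlo", se=se)


def distribution_overlap(hist_a, hist_b) -> float:
    """Histogram intersection of two count distributions, in percent."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share their support")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty histogram")
    return float(100.0 * np.minimum(a / a.sum(), b / b.sum()).sum())


def plot_row_stack(rows, bands_per_row, path, dpi: int = 120) -> None:
    """Heatmap export of a row stack, each bin colored by its class hue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = list(rows)
    if hasattr(bands_per_row, "centers"):
        bands_per_row = [bands_per_row] * len(rows)
    img = np.stack([
        hue_to_rgb(b.centers[_as_mode_row(r)])
        for r, b in zip(rows, bands_per_row)
    ])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_xlabel("spectrum bin")
    ax.set_ylabel("run")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def plot_transition_count(tc: TransitionCount, path, borders=None,
                          dpi: int = 120) -> None:
    """Raw and smoothed transition counts, with optional border markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    edges = np.arange(tc.n_bins) / tc.n_bins
    ax.plot(edges, tc.raw, color="0.6", lw=0.8, label="raw")
    ax.plot(edges, tc.smoothed, color="tab:blue", lw=1.6, label="smoothed")
    if borders is not None:
        for p in np.atleast_1d(getattr(borders, "positions", borders)):
            ax.axvline(p, color="tab:red", ls=":", lw=1)
    ax.set_xlabel("hue")
    ax.set_ylabel("transition count")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
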