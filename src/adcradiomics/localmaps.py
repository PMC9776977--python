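"""Sliding-window first-order feature maps over the prostate gland.

Each gland pixel is assigned ten first-order statistics of the ADC values
in a square window centred on it (default 9x9), restricted to window pixels
that themselves lie inside the gland.  The result is a set of ten
"parametric maps" (mean, median, kurtosis, skewness, entropy, uniformity,
interquartile range, coefficient of variation, standard deviation, median
absolute deviation) that can be rendered as colorimetric overlays and later
summarised per lesion.

Conventions (fixed, config-switchable where noted):

* variance uses the population denominator ``n`` (texture-analysis
  convention; ``ddof`` switchable),
* kurtosis is Pearson kurtosis ``m4/m2**2`` (non-excess; a Gaussian scores
  3), skewness is the moment coefficient ``m3/m2**1.5``,
* entropy (bits) and uniformity use a fixed equal-width histogram of
  ``bins`` bins (default 32) spanning the gland-wide intensity range of the
  image, shared by every window so that windows are comparable,
* percentiles interpolate linearly between closest ranks,
* a map pixel is *defined* only where the window retains at least
  ``min_support`` (default 0.5) of its pixels inside the gland.

Degenerate inputs follow fixed conventions: a constant window has skewness
0 and kurtosis 3; a zero-mean window has cv 0.  Both cases are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import ADCImage, ROIMask, check_alignment

logger = logging.getLogger(__name__)

#: The ten local first-order statistics, in canonical order.
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "kurtosis",
    "skewness",
    "entropy",
    "uniformity",
    "iqr",
    "cv",
    "std",
    "mad",
)

DEFAULT_WINDOW = 9
DEFAULT_BINS = 32
DEFAULT_MIN_SUPPORT = 0.5


@dataclass
class ParametricMapSet:
    """The ten local feature maps of one ADC image.

    ``maps[name]`` is a float grid of the image's shape, NaN where
    undefined; ``defined_mask`` marks pixels where all maps are defined.
    """

    maps: Mapping[str, np.ndarray]
    window_size: int
    defined_mask: np.ndarray
    bins: int = DEFAULT_BINS
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if set(self.maps) != set(STAT_NAMES):
            raise ValueError(
                f"expected exactly the 10 canonical maps, got {sorted(self.maps)}"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def lesion_values(self, lesion: ROIMask, name: str) -> np.ndarray:
        """Defined map values inside a lesion mask (1D array)."""
        sel = lesion.mask & self.defined_mask
        return np.asarray(self.maps[name][sel], dtype=float)


# ---------------------------------------------------------------------------
# scalar statistics


def _histogram_probs(values: np.ndarray, bins: int, value_range: tuple[float, float] | None) -> np.ndarray:
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = value_range
    if hi <= lo:  # constant sample: single occupied bin
        return np.array([1.0])
    idx = np.clip(((values - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return counts / counts.sum()


def first_order_stat(
    values: Iterable[float],
    stat_name: str,
    *,
    bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] | None = None,
    ddof: int = 0,
    excess_kurtosis: bool = False,
) -> float:
    """One first-order statistic of a 1D sample of pixel intensities.

    ``value_range`` fixes the histogram support for entropy/uniformity;
    by default the sample's own min-max range is used.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    if stat_name == "mean":
        return float(x.mean())
    if stat_name == "median":
        return float(np.median(x))
    if stat_name == "std":
        return float(x.std(ddof=ddof))
    if stat_name == "cv":
        m = x.mean()
        if m == 0:
            logger.debug("cv undefined for zero-mean sample; returning 0 by convention")
            return 0.0
        return float(x.std(ddof=ddof) / m)
    if stat_name == "iqr":
        q25, q75 = np.percentile(x, [25, 75])
        return float(q75 - q25)
    if stat_name == "mad":
        return float(np.median(np.abs(x - np.median(x))))
    if stat_name in ("skewness", "kurtosis"):
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        if m2 == 0:
            logger.debug("%s undefined for constant sample; using convention", stat_name)
            return 0.0 if stat_name == "skewness" else (0.0 if excess_kurtosis else 3.0)
        if stat_name == "skewness":
            return float(((x - m) ** 3).mean() / m2**1.5)
        k = ((x - m) ** 4).mean() / m2**2
        return float(k - 3.0 if excess_kurtosis else k)
    if stat_name in ("entropy", "uniformity"):
        p = _histogram_probs(x, bins, value_range)
        p = p[p > 0]
        if stat_name == "entropy":
            return float(-(p * np.log2(p)).sum())
        return float((p**2).sum())
    raise ValueError(f"unknown statistic {stat_name!r}; expected one of {STAT_NAMES}")


# ---------------------------------------------------------------------------
# vectorized window engine


def _window_stack(pixels: np.ndarray, gland: np.ndarray, window: int) -> np.ndarray:
    """(n_gland_pixels, window**2) array of in-gland window values, NaN-padded."""
    half = window // 2
    masked = np.where(gland, pixels.astype(float), np.nan)
    padded = np.pad(masked, half, constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    rows, cols = np.nonzero(gland)
    return view[rows, cols].reshape(len(rows), window * window)


def _row_percentile(sorted_rows: np.ndarray, n_valid: np.ndarray, q: float) -> np.ndarray:
    """Linear-interpolation percentile per row of a NaN-last sorted array."""
    pos = q / 100.0 * (n_valid - 1)
    lower = np.floor(pos).astype(int)
    upper = np.minimum(lower + 1, n_valid - 1)
    frac = pos - lower
    lo = np.take_along_axis(sorted_rows, lower[:, None], axis=1)[:, 0]
    hi = np.take_along_axis(sorted_rows, upper[:, None], axis=1)[:, 0]
    return lo * (1 - frac) + hi * frac


def _row_stats(
    windows: np.ndarray,
    bins: int,
    value_range: tuple[float, float],
    ddof: int,
    excess_kurtosis: bool,
) -> dict[str, np.ndarray]:
    """All ten statistics for each row of a (n, w*w) NaN-padded stack."""
    valid = np.isfinite(windows)
    n = valid.sum(axis=1)
    filled = np.where(valid, windows, 0.0)

    mean = filled.sum(axis=1) / n
    dev = np.where(valid, windows - mean[:, None], 0.0)
    m2 = (dev**2).sum(axis=1) / n
    m3 = (dev**3).sum(axis=1) / n
    m4 = (dev**4).sum(axis=1) / n
    if ddof:
        var = (dev**2).sum(axis=1) / np.maximum(n - ddof, 1)
    else:
        var = m2
    std = np.sqrt(var)

    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1) ** 2, 3.0)
        cv = np.where(mean != 0, std / np.where(mean != 0, mean, 1), 0.0)
    if excess_kurtosis:
        kurt = kurt - 3.0

    srt = np.sort(windows, axis=1)  # NaN sorts last
    median = _row_percentile(srt, n, 50)
    iqr = _row_percentile(srt, n, 75) - _row_percentile(srt, n, 25)
    abs_dev = np.abs(windows - median[:, None])
    mad = _row_percentile(np.sort(abs_dev, axis=1), n, 50)

    lo, hi = value_range
    if hi > lo:
        idx = np.clip(((filled - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
        counts = np.zeros((windows.shape[0], bins))
        rows = np.broadcast_to(np.arange(windows.shape[0])[:, None], idx.shape)
        np.add.at(counts, (rows[valid], idx[valid]), 1.0)
        p = counts / n[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0.0)
        entropy = -plogp.sum(axis=1)
        uniformity = (p**2).sum(axis=1)
    else:  # constant image: one occupied bin everywhere
        entropy = np.zeros(windows.shape[0])
        uniformity = np.ones(windows.shape[0])

    return {
        "mean": mean,
        "median": median,
        "kurtosis": kurt,
        "skewness": skew,
        "entropy": entropy,
        "uniformity": uniformity,
        "iqr": iqr,
        "cv": cv,
        "std": std,
        "mad": mad,
    }


def compute_all_local_maps(
    image: ADCImage,
    gland: ROIMask,
    window_size: int = DEFAULT_WINDOW,
    *,
    bins: int = DEFAULT_BINS,
    min_support: float = DEFAULT_MIN_SUPPORT,
    ddof: int = 0,
    excess_kurtosis: bool = False,
) -> ParametricMapSet:
    """Compute the ten local feature maps of an ADC image over its gland.

    Every gland pixel whose window retains at least ``min_support`` of its
    pixels inside the gland receives all ten statistics of those in-gland
    window values; other pixels are NaN and excluded from ``defined_mask``.
    """
    check_alignment(image, gland)
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window size must be an odd integer >= 3, got {window_size}")
    if window_size > min(image.shape):
        raise ValueError(f"window {window_size} does not fit image {image.shape}")
    if not gland.mask.any():
        raise ValueError("gland mask is empty")

    windows = _window_stack(image.pixels, gland.mask, window_size)
    n_valid = np.isfinite(windows).sum(axis=1)
    support_ok = n_valid >= max(2, int(np.ceil(min_support * window_size**2)))

    gland_vals = image.pixels[gland.mask]
    value_range = (float(gland_vals.min()), float(gland_vals.max()))

    stats = _row_stats(windows[support_ok], bins, value_range, ddof, excess_kurtosis)

    rows, cols = np.nonzero(gland.mask)
    defined = np.zeros(image.shape, dtype=bool)
    defined[rows[support_ok], cols[support_ok]] = True

    maps: dict[str, np.ndarray] = {}
    for name in STAT_NAMES:
        grid = np.full(image.shape, np.nan)
        grid[defined] = stats[name]
        maps[name] = grid
    return ParametricMapSet(maps, window_size, defined, bins=bins, value_range=value_range)


def compute_local_map(
    image: ADCImage,
    gland: ROIMask,
    stat_name: str,
    window_size: int = DEFAULT_WINDOW,
    **kwargs,
) -> np.ndarray:
    """One local feature map (see :func:`compute_all_local_maps`)."""
    if stat_name not in STAT_NAMES:
        raise ValueError(f"unknown statistic {stat_name!r}")
    return compute_all_local_maps(image, gland, window_size, **kwargs).maps[stat_name]
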