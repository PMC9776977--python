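"""Per-lesion radiomic feature vectors: 10 local maps x 12 global descriptors + 12 ADC descriptors = 132.

Each of the ten parametric maps is sampled inside the lesion ROI (defined
pixels only) and summarised by twelve global descriptors: the same ten
first-order statistics used for the maps, plus the mean and median of the
*last decile* — the subsample at or above the 90th percentile (inclusive,
linear-interpolation percentile, ties included).  The same twelve
descriptors computed directly on the raw ADC values inside the lesion
complete the 132-dimensional vector.

Feature names follow ``<base>-<descriptor>``: bases are the map symbols
(mu, med, k, s, e, u, IQR, cv, sigma, MAD) plus ``ADC``; descriptors are
(mean, m, kurtosis, s, entropy, u, IQR, cv, std, MAD, d-mean, d-median).
The published signature's symbols are thus ``cv-m`` (median of the local
coefficient of variation), ``mu-u`` (uniformity of the local mean),
``s-s`` (skewness of the local skewness) and ``sigma-IQR`` (IQR of the
local standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ADCImage, LesionRecord, ROIMask, check_alignment, clip_lesion_to_gland
from .localmaps import (
    DEFAULT_BINS,
    DEFAULT_WINDOW,
    STAT_NAMES,
    compute_all_local_maps,
    first_order_stat,
)

logger = logging.getLogger(__name__)

#: map statistic -> feature-name base symbol
MAP_BASES: dict[str, str] = {
    "mean": "mu",
    "median": "med",
    "kurtosis": "k",
    "skewness": "s",
    "entropy": "e",
    "uniformity": "u",
    "iqr": "IQR",
    "cv": "cv",
    "std": "sigma",
    "mad": "MAD",
}

#: the 12 global descriptors, in canonical order
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "mean",
    "m",
    "kurtosis",
    "s",
    "entropy",
    "u",
    "IQR",
    "cv",
    "std",
    "MAD",
    "d-mean",
    "d-median",
)

_DESCRIPTOR_TO_STAT = {
    "mean": "mean",
    "m": "median",
    "kurtosis": "kurtosis",
    "s": "skewness",
    "entropy": "entropy",
    "u": "uniformity",
    "IQR": "iqr",
    "cv": "cv",
    "std": "std",
    "MAD": "mad",
}

#: canonical ordering of all 132 feature names
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{MAP_BASES[stat]}-{d}" for stat in STAT_NAMES for d in DESCRIPTOR_NAMES
) + tuple(f"ADC-{d}" for d in DESCRIPTOR_NAMES)

#: aliases used in the published signature (unicode -> canonical ASCII)
SYMBOL_ALIASES: dict[str, str] = {
    "cv−m": "cv-m",
    "μ−u": "mu-u",
    "s−s": "s-s",
    "σ−IQR": "sigma-IQR",
}

MIN_LESION_PIXELS = 4


class LesionTooSmallError(ValueError):
    """Lesion has too few defined pixels for global descriptors."""


def global_descriptor(
    values: Sequence[float] | np.ndarray,
    descriptor_name: str,
    *,
    bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] | None = None,
) -> float:
    """One of the twelve global descriptors of a lesion pixel sample.

    The last-decile descriptors average (``d-mean``) or take the median of
    (``d-median``) the subsample >= the 90th percentile.  ``value_range``
    fixes the histogram support of the entropy/uniformity descriptors; the
    extraction pipeline passes the map's gland-wide range (same binning
    policy as the local maps), so that a lesion whose local means cluster
    tightly scores high uniformity regardless of the cluster's width
    relative to its own extremes.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < MIN_LESION_PIXELS:
        raise LesionTooSmallError(
            f"need >= {MIN_LESION_PIXELS} defined pixels, got {x.size}"
        )
    if descriptor_name in ("d-mean", "d-median"):
        p90 = np.percentile(x, 90)
        decile = x[x >= p90]
        return float(decile.mean() if descriptor_name == "d-mean" else np.median(decile))
    stat = _DESCRIPTOR_TO_STAT.get(descriptor_name)
    if stat is None:
        raise ValueError(f"unknown descriptor {descriptor_name!r}")
    return first_order_stat(x, stat, bins=bins, value_range=value_range)


@dataclass
class FeatureVector:
    """The 132 named radiomic features of one lesion."""

    lesion_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry exactly the {len(FEATURE_NAMES)} canonical "
                f"features in order (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features for lesion {self.lesion_id}: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[SYMBOL_ALIASES.get(name, name)]


def _descriptors_of(
    sample: np.ndarray, bins: int, value_range: tuple[float, float] | None
) -> list[float]:
    return [
        global_descriptor(sample, d, bins=bins, value_range=value_range)
        for d in DESCRIPTOR_NAMES
    ]


def _map_ranges(mapset, image: ADCImage, gland: ROIMask) -> dict[str, tuple[float, float]]:
    """Gland-wide value range of each map (and of raw ADC), for binning."""
    ranges = {}
    for stat in STAT_NAMES:
        vals = mapset.maps[stat][mapset.defined_mask]
        ranges[stat] = (float(vals.min()), float(vals.max()))
    gland_vals = image.pixels[gland.mask]
    ranges["ADC"] = (float(gland_vals.min()), float(gland_vals.max()))
    return ranges


def lesion_pixel_samples(
    image: ADCImage,
    gland: ROIMask,
    lesion: ROIMask,
    *,
    window: int = DEFAULT_WINDOW,
    bins: int = DEFAULT_BINS,
    min_support: float = 0.5,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[float, float]]]:
    """Per-map defined pixel values inside a lesion, plus raw ``ADC`` values.

    Returns ``(samples, ranges)`` where ``ranges`` holds each map's
    gland-wide value range for histogram binning.  Used directly for
    single-slice lesions and pooled across slices for multi-slice ones.
    """
    check_alignment(image, gland)
    check_alignment(image, lesion)
    lesion = clip_lesion_to_gland(lesion, gland)
    mapset = compute_all_local_maps(
        image, gland, window, bins=bins, min_support=min_support
    )
    samples = {stat: mapset.lesion_values(lesion, stat) for stat in STAT_NAMES}
    samples["ADC"] = image.pixels[lesion.mask].astype(float)
    return samples, _map_ranges(mapset, image, gland)


def feature_vector_from_samples(
    samples: dict[str, np.ndarray],
    lesion_id: str,
    *,
    bins: int = DEFAULT_BINS,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> FeatureVector:
    ranges = ranges or {}
    values: dict[str, float] = {}
    for stat in STAT_NAMES:
        sample = samples[stat]
        if sample.size < MIN_LESION_PIXELS:
            raise LesionTooSmallError(
                f"lesion {lesion_id}: only {sample.size} defined pixels on the "
                f"'{stat}' map (need >= {MIN_LESION_PIXELS})"
            )
        base = MAP_BASES[stat]
        for d, v in zip(
            DESCRIPTOR_NAMES, _descriptors_of(sample, bins, ranges.get(stat))
        ):
            values[f"{base}-{d}"] = v
    for d, v in zip(
        DESCRIPTOR_NAMES, _descriptors_of(samples["ADC"], bins, ranges.get("ADC"))
    ):
        values[f"ADC-{d}"] = v
    return FeatureVector(lesion_id, values)


def extract_feature_vector(
    image: ADCImage,
    gland: ROIMask,
    lesion: ROIMask,
    *,
    window: int = DEFAULT_WINDOW,
    bins: int = DEFAULT_BINS,
    min_support: float = 0.5,
) -> FeatureVector:
    """All 132 features of a single-slice lesion."""
    samples, ranges = lesion_pixel_samples(
        image, gland, lesion, window=window, bins=bins, min_support=min_support
    )
    return feature_vector_from_samples(
        samples, lesion.lesion_id or "lesion", bins=bins, ranges=ranges
    )


# ---------------------------------------------------------------------------
# cohort-level extraction


@dataclass
class PatientSlice:
    """One ADC slice with its gland mask and the lesion ROIs drawn on it."""

    image: ADCImage
    gland: ROIMask
    lesions: list[tuple[ROIMask, LesionRecord]]


@dataclass
class FeatureTable:
    """Lesions x 132 features with GG / csPCa labels attached.

    ``features`` is indexed by lesion_id with the canonical column order;
    ``labels`` carries gg, pirads and the binary csPCa target (GG >= 3).
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.features.columns) != list(FEATURE_NAMES):
            raise ValueError("feature table columns must be the canonical 132 names")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the same lesion index")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing cells")

    @property
    def y(self) -> np.ndarray:
        """Binary csPCa target (1 = GG >= 3)."""
        return self.labels["cspca"].to_numpy(dtype=int)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.features)

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.labels, self.features], axis=1)
        out.index.name = "lesion_id"
        out.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="lesion_id")
        label_cols = [c for c in ("patient_id", "gg", "pirads", "cspca") if c in df.columns]
        return cls(df[list(FEATURE_NAMES)], df[label_cols])


def build_feature_table(
    slices: Iterable[PatientSlice],
    *,
    window: int = DEFAULT_WINDOW,
    bins: int = DEFAULT_BINS,
    min_support: float = 0.5,
    pool_slices: bool = True,
) -> FeatureTable:
    """Extract the 132-feature vector for every lesion of a cohort.

    Lesions sharing a ``lesion_id`` across slices are pooled into one pixel
    sample before the global descriptors when ``pool_slices`` is set
    (otherwise each slice yields its own row, suffixed by slice id).
    Lesions with too few defined pixels are excluded and reported in
    ``FeatureTable.excluded`` — never silently dropped.
    """
    pooled: dict[str, dict[str, np.ndarray]] = {}
    pooled_ranges: dict[str, dict[str, tuple[float, float]]] = {}
    records: dict[str, LesionRecord] = {}
    excluded: list[tuple[str, str]] = []

    for sl in slices:
        mapset_cache = compute_all_local_maps(
            sl.image, sl.gland, window, bins=bins, min_support=min_support
        )
        slice_ranges = _map_ranges(mapset_cache, sl.image, sl.gland)
        for lesion, record in sl.lesions:
            check_alignment(sl.image, lesion)
            lesion = clip_lesion_to_gland(lesion, sl.gland)
            key = record.lesion_id if pool_slices else f"{record.lesion_id}@{sl.image.slice_id}"
            samples = {
                stat: mapset_cache.lesion_values(lesion, stat) for stat in STAT_NAMES
            }
            samples["ADC"] = sl.image.pixels[lesion.mask].astype(float)
            if key in pooled:
                pooled[key] = {
                    k: np.concatenate([pooled[key][k], samples[k]]) for k in samples
                }
                pooled_ranges[key] = {
                    k: (
                        min(pooled_ranges[key][k][0], slice_ranges[k][0]),
                        max(pooled_ranges[key][k][1], slice_ranges[k][1]),
                    )
                    for k in slice_ranges
                }
            else:
                pooled[key] = samples
                pooled_ranges[key] = slice_ranges
                records[key] = record

    rows: list[FeatureVector] = []
    for key, samples in pooled.items():
        try:
            rows.append(
                feature_vector_from_samples(
                    samples, key, bins=bins, ranges=pooled_ranges[key]
                )
            )
        except LesionTooSmallError as err:
            logger.warning("excluding lesion %s: %s", key, err)
            excluded.append((key, str(err)))

    if not rows:
        raise ValueError("no lesion passed the minimum-pixel requirement")
    features = pd.DataFrame(
        [r.values for r in rows], index=pd.Index([r.lesion_id for r in rows], name="lesion_id")
    )
    labels = pd.DataFrame(
        {
            "patient_id": [records[r.lesion_id].patient_id for r in rows],
            "gg": [records[r.lesion_id].gg for r in rows],
            "pirads": [records[r.lesion_id].pirads for r in rows],
            "cspca": [int(records[r.lesion_id].cspca) for r in rows],
        },
        index=features.index,
    )
    classes = set(labels["cspca"])
    if classes != {0, 1}:
        raise ValueError(
            f"both csPCa classes must be present, got only class(es) {sorted(classes)}"
        )
    return FeatureTable(
        features,
        labels,
        excluded=excluded,
        params={"window": window, "bins": bins, "min_support": min_support},
    )
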