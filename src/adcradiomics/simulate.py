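"""Synthetic ADC cohort generator with GG-dependent lesion texture.

No patient data accompany the analysis, so this module builds a cohort with
the statistical structure the pipeline assumes: ~102 patients carrying 117
lesions (GG counts 25/36/21/23/12), elliptical prostate glands, elliptical
lesions with pixel areas spanning [8, 1655], and a *two-level Gaussian
random field* texture: tissue is organised in units (correlated patches);
each unit carries a local mean ADC drawn from a between-unit distribution,
and pixels add within-unit Gaussian noise whose level varies smoothly
from unit to unit (optionally drawn once per lesion instead).

The two classes differ the way high- and low-grade tumours differ on ADC:

* GG >= 3 (clinically significant): spatially uniform local mean (small
  between-unit spread) with high, spatially homogeneous local variance —
  cancer cells fill whole units, so units look alike but are internally
  heterogeneous;
* GG < 3: a patchwork of units with differing means (large between-unit
  spread) and lower, heterogeneous within-unit variance — cancer
  intermingles with normal glands.

GG1 and GG2 share one texture distribution, as do GG3/4/5, so the
similarity analysis has a built-in negative control.  A ``separation``
knob linearly interpolates the high-grade parameters toward the low-grade
ones (0 = indistinguishable classes) for power studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .features import PatientSlice
from .io import ADCImage, LesionRecord, ROIMask, write_adc, write_label_table, write_mask

logger = logging.getLogger(__name__)

#: Feature families the generator's class structure drives, for recovery
#: checks.  The high-grade class is planted with *greater local dispersion*
#: (higher within-unit noise -> cv/sigma/entropy map levels and raw-ADC
#: dispersion descriptors rise, uniformity-map levels fall) and with *more
#: uniform local means* (smaller between-unit spread -> dispersion-type
#: descriptors of the local-mean and local-median maps fall).
PLANTED_DISPERSION_FEATURES = frozenset(
    {f"{b}-{d}" for b in ("cv", "sigma", "e") for d in ("mean", "m", "d-mean", "d-median")}
    | {f"u-{d}" for d in ("mean", "m", "d-mean", "d-median")}
    | {f"ADC-{d}" for d in ("std", "MAD", "IQR", "cv", "u", "entropy")}
)
PLANTED_MEAN_UNIFORMITY_FEATURES = frozenset(
    f"{b}-{d}" for b in ("mu", "med") for d in ("u", "entropy", "std", "IQR", "MAD", "cv")
)

#: PIRADS frequencies per class, matching the cohort the generator emulates
_PIRADS_PROBS = {
    "low": {3: 34 / 61, 4: 22 / 61, 5: 5 / 61},
    "high": {3: 9 / 56, 4: 35 / 56, 5: 12 / 56},
}


@dataclass
class TextureParams:
    """Two-level Gaussian random-field texture.

    The local tissue mean is a smooth Gaussian field: ``mean`` plus a
    zero-mean surface of standard deviation ``between_sigma`` correlated
    over ``unit_scale`` pixels (the "unit" size of the tissue patchwork).
    Pixels add Gaussian noise whose standard deviation itself varies
    smoothly between ``within_sigma`` bounds over the same unit scale.

    For between-unit mean heterogeneity to be visible as such at the
    analysis-window scale, units must exceed the window; low-grade lesions
    therefore default to a unit scale above 9 px.
    """

    mean: float
    between_sigma: float
    within_sigma: tuple[float, float]
    unit_scale: float = 9.0
    #: "field": the noise level varies smoothly from unit to unit (default);
    #: "region": one level per generated region — spatially uniform inside a
    #: lesion, more diverse across lesions. The region variant trades feature
    #: separation for wider high-grade score dispersion; see the methods note.
    sigma_mode: str = "field"


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ADC levels are in 1e-6 mm^2/s; tumours sit near 850-950 and the
    surrounding gland is modelled as mixed peripheral/transition tissue
    only moderately above them, so lesion-boundary contrast does not
    overwhelm the within-lesion texture.  Lesion areas follow per-class
    lognormals matched to the emulated cohort.
    """

    n_per_gg: dict[int, int] = field(
        default_factory=lambda: {1: 25, 2: 36, 3: 21, 4: 23, 5: 12}
    )
    n_patients: int = 102
    image_shape: tuple[int, int] = (112, 112)
    gland_radii: tuple[float, float] = (40.0, 32.0)
    pixel_spacing: tuple[float, float] = (0.78, 0.78)
    lesion_area_range: tuple[int, int] = (8, 1655)
    # lognormal lesion areas per class (median px, log-sigma), matched to the
    # emulated cohort's per-class size statistics (GG>=3 lesions run larger)
    area_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (98.0, 0.73), "high": (113.0, 1.05)}
    )
    background: TextureParams = field(
        default_factory=lambda: TextureParams(950.0, 80.0, (60.0, 100.0), unit_scale=9.0)
    )
    low_grade: TextureParams = field(
        default_factory=lambda: TextureParams(920.0, 190.0, (40.0, 100.0), unit_scale=14.0)
    )
    high_grade: TextureParams = field(
        default_factory=lambda: TextureParams(880.0, 25.0, (120.0, 180.0), unit_scale=9.0)
    )
    separation: float = 1.0
    noise_model: str = "gaussian"  # or "rician"
    rician_sigma: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_gg.values()):
            raise ValueError("GG counts must be non-negative")
        lo, hi = self.lesion_area_range
        if not 0 < lo < hi:
            raise ValueError("invalid lesion area range")
        if not 0.0 <= self.separation:
            raise ValueError("separation must be non-negative")

    @property
    def n_lesions(self) -> int:
        return sum(self.n_per_gg.values())

    def effective_high_grade(self) -> TextureParams:
        """High-grade texture after applying the separation knob."""
        s = self.separation
        lg, hg = self.low_grade, self.high_grade
        return TextureParams(
            lg.mean + s * (hg.mean - lg.mean),
            lg.between_sigma + s * (hg.between_sigma - lg.between_sigma),
            (
                lg.within_sigma[0] + s * (hg.within_sigma[0] - lg.within_sigma[0]),
                lg.within_sigma[1] + s * (hg.within_sigma[1] - lg.within_sigma[1]),
            ),
            unit_scale=lg.unit_scale + s * (hg.unit_scale - lg.unit_scale),
            sigma_mode=hg.sigma_mode if s > 0.5 else lg.sigma_mode,
        )

    def with_separation(self, separation: float) -> "CohortSpec":
        return replace(self, separation=separation)

    def texture_for(self, gg: int) -> TextureParams:
        return self.effective_high_grade() if gg >= 3 else self.low_grade

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        for key in ("background", "low_grade", "high_grade"):
            if key in d and isinstance(d[key], dict):
                d[key]["within_sigma"] = tuple(d[key]["within_sigma"])
                d[key] = TextureParams(**d[key])
        for key in ("image_shape", "gland_radii", "pixel_spacing", "lesion_area_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "n_per_gg" in d:
            d["n_per_gg"] = {int(k): int(v) for k, v in d["n_per_gg"].items()}
        if "area_params" in d:
            d["area_params"] = {k: tuple(v) for k, v in d["area_params"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# texture fields


def _smooth_unit_field(
    shape: tuple[int, int], unit_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian field correlated over ``unit_scale`` pixels.

    Normalized by the theoretical standard deviation of Gaussian-filtered
    white noise (not the realization's sample std, which would rescale
    small patches inconsistently).
    """
    from scipy.ndimage import gaussian_filter

    sigma = max(unit_scale / 2.0, 0.5)
    pad = int(np.ceil(4 * sigma))
    noise = rng.normal(size=(shape[0] + 2 * pad, shape[1] + 2 * pad))
    smooth = gaussian_filter(noise, sigma, mode="constant")[pad:-pad, pad:-pad]
    # separable kernel: Var(out) = (sum_i k1d(i)^2)^2 for unit-variance input
    radius = int(4 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1d = np.exp(-(x**2) / (2 * sigma**2))
    k1d /= k1d.sum()
    theoretical_sd = float((k1d**2).sum())
    return smooth / theoretical_sd


def _texture_field(
    params: TextureParams, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Two-level Gaussian field: smooth local-mean surface + varying pixel noise."""
    from scipy.stats import norm as _norm

    mean_field = params.mean + params.between_sigma * _smooth_unit_field(
        shape, params.unit_scale, rng
    )
    lo, hi = params.within_sigma
    if hi <= lo:
        sigma_field = np.full(shape, lo)
    elif params.sigma_mode == "region":
        sigma_field = np.full(shape, rng.uniform(lo, hi))
    else:
        u = _norm.cdf(_smooth_unit_field(shape, params.unit_scale, rng))
        sigma_field = lo + (hi - lo) * u
    return mean_field + rng.normal(0.0, 1.0, size=shape) * sigma_field


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _lesion_mask_patch(area: float, rng: np.random.Generator, min_area: int = 8) -> np.ndarray:
    """Axis-aligned elliptical patch mask of approximately ``area`` pixels."""
    q = rng.uniform(0.55, 0.95)  # aspect ratio
    r = np.sqrt(area / np.pi)
    a, b = r / np.sqrt(q), r * np.sqrt(q)
    if rng.random() < 0.5:
        a, b = b, a
    h, w = int(np.ceil(2 * a)) + 3, int(np.ceil(2 * b)) + 3
    patch = _ellipse_mask((h, w), ((h - 1) / 2, (w - 1) / 2), (max(a, 1.0), max(b, 1.0)))
    if patch.sum() < min_area:  # rasterization undershot: use a 3x3 block
        patch = np.zeros((5, 5), dtype=bool)
        patch[1:4, 1:4] = True
    return patch


def generate_lesion_texture(
    spec: CohortSpec, gg: int, area: float, seed: int | None = None, *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A lesion patch of ~``area`` pixels with the GG-dependent texture.

    Returns ``(values, mask)`` over the patch bounding box; values outside
    the mask are NaN.
    """
    if area < spec.lesion_area_range[0]:
        raise ValueError(f"area {area} below the minimum {spec.lesion_area_range[0]}")
    rng = rng or np.random.default_rng(seed)
    mask = _lesion_mask_patch(area, rng)
    field = _texture_field(spec.texture_for(gg), mask.shape, rng)
    values = np.where(mask, field, np.nan)
    return values, mask


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class Cohort:
    """Synthetic cohort: one slice per patient plus the lesion label list."""

    slices: list[PatientSlice]
    records: list[LesionRecord]
    spec: CohortSpec

    def __iter__(self) -> Iterator[PatientSlice]:
        return iter(self.slices)

    @property
    def n_lesions(self) -> int:
        return len(self.records)

    def save(self, directory: str | Path) -> None:
        """Write TIFF images, PNG masks, the label CSV and the spec YAML."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sl in self.slices:
            pid = sl.image.patient_id
            write_adc(sl.image, directory / f"{pid}_adc.tif")
            write_mask(sl.gland, directory / f"{pid}_gland.png")
            for lesion, record in sl.lesions:
                write_mask(lesion, directory / f"{record.lesion_id}_mask.png")
        write_label_table(self.records, directory / "labels.csv")
        self.spec.to_yaml(directory / "cohort_spec.yaml")

    @classmethod
    def load(cls, directory: str | Path) -> "Cohort":
        from .io import read_adc, read_label_table, read_mask

        directory = Path(directory)
        records = read_label_table(directory / "labels.csv")
        spec = CohortSpec.from_yaml(directory / "cohort_spec.yaml")
        by_patient: dict[str, list[LesionRecord]] = {}
        for r in records:
            by_patient.setdefault(r.patient_id, []).append(r)
        slices = []
        for pid, recs in by_patient.items():
            image = read_adc(
                directory / f"{pid}_adc.tif",
                pixel_spacing=spec.pixel_spacing,
                patient_id=pid,
            )
            gland = read_mask(directory / f"{pid}_gland.png", role="gland")
            lesions = [
                (read_mask(directory / f"{r.lesion_id}_mask.png", role="lesion",
                           lesion_id=r.lesion_id), r)
                for r in recs
            ]
            slices.append(PatientSlice(image, gland, lesions))
        return cls(slices, records, spec)


def _sample_areas(
    spec: CohortSpec, gg_list: list[int], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = spec.lesion_area_range
    areas = np.empty(len(gg_list))
    for i, gg in enumerate(gg_list):
        med, sig = spec.area_params["high" if gg >= 3 else "low"]
        areas[i] = np.exp(rng.normal(np.log(med), sig))
    return np.clip(areas, lo + 1, hi - 60)  # headroom for rasterization error


def _sample_pirads(gg: int, rng: np.random.Generator) -> int:
    probs = _PIRADS_PROBS["high" if gg >= 3 else "low"]
    return int(rng.choice(list(probs), p=list(probs.values())))


def _place_lesion(
    gland: np.ndarray, occupied: np.ndarray, patch: np.ndarray, rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[int, int] | None:
    """Top-left corner such that the patch fits inside the gland, off other lesions."""
    h, w = patch.shape
    H, W = gland.shape
    if h > H or w > W:
        return None
    rows, cols = np.nonzero(gland)
    for _ in range(max_tries):
        r0 = rng.integers(0, H - h + 1)
        c0 = rng.integers(0, W - w + 1)
        region_ok = gland[r0 : r0 + h, c0 : c0 + w]
        region_busy = occupied[r0 : r0 + h, c0 : c0 + w]
        if np.all(region_ok[patch]) and not np.any(region_busy[patch]):
            return int(r0), int(c0)
    return None


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Build the full synthetic cohort (images, masks, labels) from a spec.

    Lesions are assigned so that patients hosting two lesions receive the
    smaller ones, which keeps placement inside the gland feasible; a lesion
    that cannot be placed after 100 tries raises.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n_lesions = spec.n_lesions
    if n_lesions < spec.n_patients:
        raise ValueError("more patients than lesions")

    gg_list = [g for g, n in sorted(spec.n_per_gg.items()) for _ in range(n)]
    order = rng.permutation(n_lesions)
    gg_list = [gg_list[i] for i in order]
    areas = _sample_areas(spec, gg_list, rng)

    # largest lesions get their own patient; the smallest share
    by_area = np.argsort(-areas)
    assignment: dict[int, list[int]] = {p: [] for p in range(spec.n_patients)}
    for p, li in enumerate(by_area[: spec.n_patients]):
        assignment[p].append(int(li))
    extras = by_area[spec.n_patients :]
    for k, li in enumerate(extras):
        assignment[spec.n_patients - 1 - k].append(int(li))

    slices: list[PatientSlice] = []
    records: list[LesionRecord] = []
    H, W = spec.image_shape
    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        pixels = _texture_field(spec.background, (H, W), rng)
        jitter = rng.uniform(0.92, 1.0, size=2)
        gland_mask = _ellipse_mask(
            (H, W), ((H - 1) / 2, (W - 1) / 2),
            (spec.gland_radii[0] * jitter[0], spec.gland_radii[1] * jitter[1]),
        )
        occupied = np.zeros((H, W), dtype=bool)
        lesions: list[tuple[ROIMask, LesionRecord]] = []
        for li in assignment[p]:
            gg = gg_list[li]
            patch = _lesion_mask_patch(areas[li], rng)
            corner = _place_lesion(gland_mask, occupied, patch, rng)
            if corner is None:
                raise RuntimeError(
                    f"could not place lesion of ~{areas[li]:.0f} px in patient {pid}"
                )
            r0, c0 = corner
            field = _texture_field(spec.texture_for(gg), patch.shape, rng)
            region = pixels[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]]
            region[patch] = field[patch]
            mask = np.zeros((H, W), dtype=bool)
            mask[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]] = patch
            occupied |= mask
            record = LesionRecord(
                lesion_id=f"L{li:03d}", patient_id=pid, gg=gg,
                pirads=_sample_pirads(gg, rng),
            )
            record.area_mm2 = float(mask.sum() * spec.pixel_spacing[0] * spec.pixel_spacing[1])
            lesions.append((ROIMask(mask, role="lesion", lesion_id=record.lesion_id), record))
            records.append(record)
        if spec.noise_model == "rician":
            e1 = rng.normal(0.0, spec.rician_sigma, size=(H, W))
            e2 = rng.normal(0.0, spec.rician_sigma, size=(H, W))
            pixels = np.sqrt((pixels + e1) ** 2 + e2**2)
        pixels = np.clip(pixels, 1.0, None)
        image = ADCImage(pixels, spec.pixel_spacing, patient_id=pid, slice_id=f"{pid}-s0")
        slices.append(PatientSlice(image, ROIMask(gland_mask, role="gland"), lesions))

    areas_px = np.array([r.area_mm2 for r in records]) / (
        spec.pixel_spacing[0] * spec.pixel_spacing[1]
    )
    lo, hi = spec.lesion_area_range
    assert areas_px.min() >= lo and areas_px.max() <= hi, "lesion area out of range"
    logger.info(
        "generated %d patients / %d lesions (areas %d-%d px)",
        spec.n_patients, len(records), areas_px.min(), areas_px.max(),
    )
    return Cohort(slices, records, spec)
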