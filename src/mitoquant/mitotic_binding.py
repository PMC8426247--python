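"""Quantification of mitotic chromatin binding from image pairs.

The procedure turns an interphase image and the following metaphase image
of the same nucleus into a per-nucleus chromatin-zone enrichment, and a
set of nuclei per transgenic line into a "% mitotic binding" relative to
a reference line (the wild-type fusion, set to 100%):

1. estimate the interphase nucleus diameter and rescale both frames so
   the interphase nucleus is 37 px across (the metaphase nuclear area is
   then 52 px across);
2. measure total signal in circular areas of 37 px (interphase) and
   52 px (metaphase) diameter;
3. extract a 46 x 16 px intensity profile with its long axis
   perpendicular to the metaphase plate (axis estimated from image
   moments, or supplied for non-binders);
4. normalize the 46-point profile so its area equals the metaphase total
   signal;
5. sum the profile above the nucleoplasmic baseline (mean of the flank
   positions) over the chromatin zone, profile positions 16-30 (1-based);
6. express the per-line mean enrichment as a percentage of the
   reference line's mean enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import rescale as _sk_rescale

__all__ = [
    "NucleusFramePair",
    "IntensityProfile",
    "NucleusMeasurement",
    "BindingResult",
    "PROFILE_LENGTH",
    "PROFILE_WIDTH",
    "ZONE_POSITIONS",
    "INTERPHASE_DIAMETER",
    "METAPHASE_DIAMETER",
    "estimate_interphase_diameter",
    "rescale_pair",
    "total_signal",
    "retention_ratio",
    "estimate_plate_axis",
    "extract_profile",
    "normalize_profile",
    "zone_enrichment",
    "percent_mitotic_binding",
    "quantify_pair",
    "quantify_lines",
]

# Geometry of the measurement, at the common rescaled resolution.
INTERPHASE_DIAMETER = 37.0
METAPHASE_DIAMETER = 52.0
PROFILE_LENGTH = 46
PROFILE_WIDTH = 16
# Chromatin zone: profile positions 16..30 inclusive, 1-based.
ZONE_POSITIONS = (16, 30)


class NoNucleusError(ValueError):
    """Raised when no nucleus can be segmented from an image."""


class AxisUndeterminedError(ValueError):
    """Raised when the plate axis cannot be estimated and none was supplied."""


@dataclass
class NucleusFramePair:
    """One interphase image with its following metaphase image."""

    interphase_image: np.ndarray
    metaphase_image: np.ndarray
    pixel_size_nm: float = 100.0
    interphase_center: tuple[float, float] | None = None  # (x, y)
    metaphase_center: tuple[float, float] | None = None
    plate_axis_angle: float | None = None  # long axis of the plate; None = auto
    cycle: int | None = None

    def __post_init__(self) -> None:
        for name in ("interphase_image", "metaphase_image"):
            img = np.asarray(getattr(self, name), dtype=float)
            if img.ndim != 2:
                raise ValueError(f"{name} must be 2-D")
            setattr(self, name, img)
        for name in ("interphase_center", "metaphase_center"):
            c = getattr(self, name)
            if c is not None:
                x, y = c
                h, w = self.metaphase_image.shape
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(f"{name} {c} outside image bounds")


@dataclass
class IntensityProfile:
    """46-point averaged intensity profile across the metaphase plate."""

    values: np.ndarray
    normalization: str = "raw"  # "raw" | "normalized"
    source_total_metaphase: float | None = None
    padded: bool = False  # True if the sampling rectangle left the image

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (PROFILE_LENGTH,):
            raise ValueError(f"profile must have exactly {PROFILE_LENGTH} values")


@dataclass
class NucleusMeasurement:
    """Per-nucleus quantification output."""

    interphase_diameter: float
    total_interphase: float
    total_metaphase: float
    retention: float
    profile_axis: float
    profile: IntensityProfile
    enrichment: float


@dataclass
class BindingResult:
    """Per-line % mitotic binding relative to the reference line."""

    per_nucleus_enrichment: np.ndarray
    mean_profile: IntensityProfile | None
    percent_of_reference: float
    sd: float
    n_nuclei: int
    n_embryos: int = 0


def estimate_interphase_diameter(image: np.ndarray) -> float:
    """Equivalent-circle diameter of the largest segmented component.

    Thresholds the image (Otsu), labels connected components above the
    threshold and returns ``2*sqrt(area/pi)`` of the largest one.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0 or np.ptp(image) == 0:
        raise NoNucleusError("flat or empty image: no nucleus found")
    mask = image > threshold_otsu(image)
    if not mask.any():
        raise NoNucleusError("no pixels above threshold")
    regions = regionprops(label(mask))
    area = max(r.area for r in regions)
    return 2.0 * np.sqrt(area / np.pi)


def rescale_pair(
    pair: NucleusFramePair, measured_diameter: float, target: float = INTERPHASE_DIAMETER
) -> NucleusFramePair:
    """Resample both frames so the interphase nucleus is ``target`` px wide.

    Intensities are divided by the squared zoom factor so total signal is
    preserved up to interpolation error.
    """
    if measured_diameter <= 0:
        raise ValueError("measured diameter must be positive")
    factor = target / measured_diameter
    if factor == 1.0:
        return pair

    def scale_image(img: np.ndarray) -> np.ndarray:
        out = _sk_rescale(img, factor, order=1, preserve_range=True, anti_aliasing=factor < 1)
        return out / factor**2

    def scale_center(c: tuple[float, float] | None) -> tuple[float, float] | None:
        if c is None:
            return None
        return ((c[0] + 0.5) * factor - 0.5, (c[1] + 0.5) * factor - 0.5)

    return replace(
        pair,
        interphase_image=scale_image(pair.interphase_image),
        metaphase_image=scale_image(pair.metaphase_image),
        interphase_center=scale_center(pair.interphase_center),
        metaphase_center=scale_center(pair.metaphase_center),
    )


def _default_center(image: np.ndarray) -> tuple[float, float]:
    h, w = image.shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def total_signal(
    image: np.ndarray, center: tuple[float, float] | None, diameter: float
) -> float:
    """Sum of pixel values whose centers lie inside the given disk."""
    image = np.asarray(image, dtype=float)
    if center is None:
        center = _default_center(image)
    cx, cy = center
    r = diameter / 2.0
    h, w = image.shape
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
        raise ValueError("measurement disk extends beyond the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return float(image[mask].sum())


def retention_ratio(pair: NucleusFramePair) -> float:
    """Metaphase / interphase total signal of an already-rescaled pair.

    Totals are measured in the stated circular areas (37 px interphase,
    52 px metaphase).  Values near 1 indicate that the protein stays in
    the perinuclear volume during mitosis.
    """
    ti = total_signal(pair.interphase_image, pair.interphase_center, INTERPHASE_DIAMETER)
    tm = total_signal(pair.metaphase_image, pair.metaphase_center, METAPHASE_DIAMETER)
    if ti == 0:
        raise ZeroDivisionError("zero interphase total signal")
    return tm / ti


def estimate_plate_axis(
    metaphase_image: np.ndarray,
    center: tuple[float, float] | None = None,
    zone_diameter: float = METAPHASE_DIAMETER,
    min_anisotropy: float = 1.2,
) -> float:
    """Profile axis (degrees) perpendicular to the metaphase plate.

    The plate orientation is taken as the principal axis of the
    intensity-weighted second moments of above-threshold pixels within
    the metaphase zone; the profile axis is that orientation + 90 deg.
    Raises :class:`AxisUndeterminedError` for flat or isotropic zones,
    for which a user-supplied axis is required.
    """
    image = np.asarray(metaphase_image, dtype=float)
    if center is None:
        center = _default_center(image)
    cx, cy = center
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    zone = (xx - cx) ** 2 + (yy - cy) ** 2 <= (zone_diameter / 2.0) ** 2
    vals = image[zone]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise AxisUndeterminedError("flat metaphase zone: supply the plate axis")
    thr = threshold_otsu(vals)
    sel = zone & (image > thr)
    if not sel.any():
        raise AxisUndeterminedError("no pixels above threshold: supply the plate axis")
    wgt = image[sel]
    x = xx[sel] - np.average(xx[sel], weights=wgt)
    y = yy[sel] - np.average(yy[sel], weights=wgt)
    mxx = np.average(x * x, weights=wgt)
    myy = np.average(y * y, weights=wgt)
    mxy = np.average(x * y, weights=wgt)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[1] / max(evals[0], 1e-30) < min_anisotropy:
        raise AxisUndeterminedError("isotropic intensity distribution: supply the plate axis")
    vx, vy = evecs[:, 1]  # principal (largest-variance) axis = plate long axis
    plate_angle = np.rad2deg(np.arctan2(vy, vx))
    return (plate_angle + 90.0) % 180.0


def extract_profile(
    metaphase_image: np.ndarray,
    center: tuple[float, float] | None,
    profile_axis: float,
) -> IntensityProfile:
    """Mean intensity along a 46 x 16 px rectangle at ``profile_axis``.

    Position ``i`` (1-based 1..46) is the mean of 16 bilinear samples
    taken across the rectangle at longitudinal offset ``i - 23.5`` from
    the center.  Samples outside the image read as 0 and set the
    ``padded`` flag.
    """
    image = np.asarray(metaphase_image, dtype=float)
    if center is None:
        center = _default_center(image)
    cx, cy = center
    th = np.deg2rad(profile_axis)
    eu = np.array([np.cos(th), np.sin(th)])    # along the profile
    ev = np.array([-np.sin(th), np.cos(th)])   # across
    u = np.arange(PROFILE_LENGTH) - (PROFILE_LENGTH - 1) / 2.0
    v = np.arange(PROFILE_WIDTH) - (PROFILE_WIDTH - 1) / 2.0
    uu, vv = np.meshgrid(u, v, indexing="ij")
    px = cx + uu * eu[0] + vv * ev[0]
    py = cy + uu * eu[1] + vv * ev[1]
    h, w = image.shape
    padded = bool(
        (px < 0).any() or (py < 0).any() or (px > w - 1).any() or (py > h - 1).any()
    )
    samples = ndimage.map_coordinates(
        image, np.stack([py.ravel(), px.ravel()]), order=1, mode="constant", cval=0.0
    ).reshape(PROFILE_LENGTH, PROFILE_WIDTH)
    return IntensityProfile(values=samples.mean(axis=1), normalization="raw", padded=padded)


def normalize_profile(profile: IntensityProfile, total_metaphase: float) -> IntensityProfile:
    """Scale the profile so its area equals the metaphase total signal.

    Idempotent: re-normalizing to the same total leaves the profile
    unchanged.
    """
    s = profile.values.sum()
    if s <= 0:
        raise ValueError("cannot normalize a profile with non-positive sum")
    return IntensityProfile(
        values=profile.values * (total_metaphase / s),
        normalization="normalized",
        source_total_metaphase=total_metaphase,
        padded=profile.padded,
    )


def zone_enrichment(profile: IntensityProfile, baseline: str = "mean") -> float:
    """Signal in the chromatin zone above the nucleoplasmic baseline.

    The baseline is the mean (or median) of the flank positions
    (1..15 and 31..46, 1-based); the enrichment is the sum of
    (value - baseline) over zone positions 16..30.  May be negative for
    non-binders; reported as-is.
    """
    lo, hi = ZONE_POSITIONS
    zone = profile.values[lo - 1 : hi]
    flanks = np.concatenate([profile.values[: lo - 1], profile.values[hi:]])
    b = np.median(flanks) if baseline == "median" else flanks.mean()
    return float((zone - b).sum())


def percent_mitotic_binding(
    variant_enrichments: np.ndarray,
    reference_enrichments: np.ndarray,
    n_embryos: int = 0,
    mean_profile: IntensityProfile | None = None,
) -> BindingResult:
    """% mitotic binding of a variant line relative to the reference.

    ``100 * mean(variant) / mean(reference)``; the standard deviation is
    taken over all nuclei of the variant line (scaled to the same
    percentage units).  A non-positive variant mean is floored at 0%
    with a warning; a non-positive reference mean is an error.
    """
    variant = np.asarray(variant_enrichments, dtype=float)
    reference = np.asarray(reference_enrichments, dtype=float)
    if variant.size < 1 or reference.size < 1:
        raise ValueError("need at least one nucleus per line")
    ref_mean = reference.mean()
    if ref_mean <= 0:
        raise ValueError("reference line has non-positive mean enrichment")
    pct = 100.0 * variant.mean() / ref_mean
    if pct < 0:
        warnings.warn("negative mean enrichment floored at 0% (non-binder)")
        pct = 0.0
    sd = 100.0 * variant.std(ddof=1) / ref_mean if variant.size > 1 else 0.0
    return BindingResult(
        per_nucleus_enrichment=variant,
        mean_profile=mean_profile,
        percent_of_reference=pct,
        sd=sd,
        n_nuclei=int(variant.size),
        n_embryos=n_embryos,
    )


def quantify_pair(
    pair: NucleusFramePair,
    target_diameter: float = INTERPHASE_DIAMETER,
    zone_diameter: float = METAPHASE_DIAMETER,
    background_percentile: float | None = None,
    baseline: str = "mean",
) -> NucleusMeasurement:
    """Run the full per-nucleus quantification on one image pair.

    Optionally subtracts a flat background (the given image percentile)
    from both frames before measuring.
    """
    if background_percentile is not None:
        pair = replace(
            pair,
            interphase_image=np.clip(
                pair.interphase_image
                - np.percentile(pair.interphase_image, background_percentile),
                0,
                None,
            ),
            metaphase_image=np.clip(
                pair.metaphase_image
                - np.percentile(pair.metaphase_image, background_percentile),
                0,
                None,
            ),
        )
    d = estimate_interphase_diameter(pair.interphase_image)
    scaled = rescale_pair(pair, d, target_diameter)
    ti = total_signal(scaled.interphase_image, scaled.interphase_center, target_diameter)
    tm = total_signal(scaled.metaphase_image, scaled.metaphase_center, zone_diameter)
    if scaled.plate_axis_angle is not None:
        profile_axis = (scaled.plate_axis_angle + 90.0) % 180.0
    else:
        profile_axis = estimate_plate_axis(
            scaled.metaphase_image, scaled.metaphase_center, zone_diameter
        )
    profile = extract_profile(scaled.metaphase_image, scaled.metaphase_center, profile_axis)
    norm = normalize_profile(profile, tm)
    return NucleusMeasurement(
        interphase_diameter=d,
        total_interphase=ti,
        total_metaphase=tm,
        retention=tm / ti if ti else np.nan,
        profile_axis=profile_axis,
        profile=norm,
        enrichment=zone_enrichment(norm, baseline=baseline),
    )


def quantify_lines(
    pairs_by_line: dict[str, list[NucleusFramePair]],
    reference_line: str,
    **kwargs,
) -> dict[str, BindingResult]:
    """Quantify every nucleus of every line and express each line as a
    percentage of the reference line (which reports 100% by construction).
    """
    if reference_line not in pairs_by_line:
        raise KeyError(f"reference line {reference_line!r} not in input")
    enr: dict[str, np.ndarray] = {}
    prof: dict[str, IntensityProfile] = {}
    for line, pairs in pairs_by_line.items():
        ms = [quantify_pair(p, **kwargs) for p in pairs]
        enr[line] = np.array([m.enrichment for m in ms])
        prof[line] = IntensityProfile(
            values=np.mean([m.profile.values for m in ms], axis=0),
            normalization="normalized",
        )
    out = {}
    for line in pairs_by_line:
        out[line] = percent_mitotic_binding(
            enr[line], enr[reference_line], mean_profile=prof[line]
        )
    return out
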