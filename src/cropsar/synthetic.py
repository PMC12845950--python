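"""Synthetic multi-temporal SAR / optical scene generator.

Stands in for a season of dual-pol SAR and multispectral optical
acquisitions over an 8-class agricultural landscape, so that every
downstream stage (covariance conditioning, polarimetric decomposition,
feature fusion, classification, accuracy assessment) is testable without
any satellite download.

The generator draws rectangular field patches on a background class, then
renders, per acquisition date:

* **SAR**: each class carries a per-date scattering state (volume power
  ``mv``, polarized power ``ms``, polarized-component orientation ``alpha``
  and phase ``delta``).  The true per-pixel Stokes vector is
  ``s = mv*sv + ms*sp`` (the exact model the decomposition inverts); its
  covariance equivalent is speckled by averaging L independent single-look
  outer products of zero-mean circular complex Gaussian channel pairs —
  the fully-developed-speckle model, giving complex-Wishart distributed
  covariances whose expectation is the true covariance.

* **Optical**: each class carries a per-date 12-band mean reflectance
  (a phenology-driven mixture of vegetation / soil / water / built-up
  spectra); pixels get additive Gaussian noise, and optional contiguous
  cloud patches overwrite reflectance with a bright class-independent
  value, recorded in a cloud mask.

Default profiles encode one growing season: rice transplanted into flooded
fields in late spring and peaking in August; soybean and corn sown in
April and harvested by late August; perennial ramie with a long flat
season; stable water, forest, grassland and building covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import box

from .legend import (
    CLASS_CODES,
    CLASS_NAMES,
    OPTICAL_BAND_NAMES,
    OPTICAL_DATES,
    SAR_DATES,
    day_of_year,
)
from .optical import BAND_RESOLUTION, OpticalScene
from .samples import FieldPolygon, SamplePolygons
from .sar import C2Raster, StokesRaster, stokes_to_c2

__all__ = [
    "PlacementError",
    "LandCoverMap",
    "ScatteringParams",
    "CropScatteringProfile",
    "CropReflectanceProfile",
    "default_scattering_profile",
    "default_reflectance_profile",
    "generate_landcover",
    "simulate_sar_scene",
    "simulate_optical_scene",
    "sample_polygons",
]


class PlacementError(RuntimeError):
    """Raised when the requested fields cannot be placed in the extent."""


@dataclass
class LandCoverMap:
    """Per-pixel class labels plus the field polygons used to draw them."""

    labels: np.ndarray  # (rows, cols) int class codes
    polygons: list[FieldPolygon]
    pixel_size: float = 10.0
    background: int = CLASS_CODES["grassland"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def present_classes(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())


# --------------------------------------------------------------------------
# land cover
# --------------------------------------------------------------------------

def generate_landcover(
    extent: tuple[int, int],
    fields_per_class: int | dict = 1,
    seed: int = 0,
    field_size: tuple[int, int] | dict = (5, 10),
    background: int | str = "grassland",
) -> LandCoverMap:
    """Draw rectangular field patches for all 8 classes on a background.

    Parameters
    ----------
    extent : (rows, cols)
        Grid size; at least 32 x 32.
    fields_per_class : int or {class -> int}
        Number of fields per class (keys may be codes or names).
    field_size : (lo, hi) or {class -> (lo, hi)}
        Inclusive range of field side lengths in pixels.
    background : class code or name
        Class filling pixels not covered by a field.

    Fields are placed uniformly at random without overlap (1-pixel margin);
    the same seed reproduces the same map bit for bit.
    """
    rows, cols = extent
    if rows < 32 or cols < 32:
        raise ValueError("extent must be at least 32 x 32 pixels")
    bg = CLASS_CODES[background] if isinstance(background, str) else int(background)

    def per_class(value, default):
        if isinstance(value, dict):
            out = {}
            for code in CLASS_NAMES:
                key = code if code in value else CLASS_NAMES[code]
                out[code] = value.get(key, default)
            return out
        return {code: value for code in CLASS_NAMES}

    counts = per_class(fields_per_class, 1)
    sizes = per_class(field_size, (5, 10))

    rng = np.random.default_rng(seed)
    labels = np.full((rows, cols), bg, dtype=np.int16)
    occupied = np.zeros((rows, cols), dtype=bool)
    polygons: list[FieldPolygon] = []

    def place(code: int, h: int, w: int) -> bool:
        """Draw one h x w field at a uniformly random admissible position.

        Admissible positions (1-pixel margin kept free) are found exactly
        with an integral image, so placement only fails when no free slot
        of this size exists anywhere.
        """
        if h + 2 > rows or w + 2 > cols:
            return False
        ii = np.zeros((rows + 1, cols + 1), dtype=np.int64)
        ii[1:, 1:] = occupied.cumsum(0).cumsum(1)
        hh, ww = h + 2, w + 2  # field plus margin
        # window sum of occupancy for every top-left margin corner
        sums = (
            ii[hh:, ww:] - ii[:-hh, ww:] - ii[hh:, :-ww] + ii[:-hh, :-ww]
        )
        free_r, free_c = np.nonzero(sums == 0)
        if len(free_r) == 0:
            return False
        k = int(rng.integers(len(free_r)))
        r0, c0 = int(free_r[k]) + 1, int(free_c[k]) + 1
        labels[r0 : r0 + h, c0 : c0 + w] = code
        occupied[r0 : r0 + h, c0 : c0 + w] = True
        polygons.append(FieldPolygon(code, box(c0, r0, c0 + w, r0 + h)))
        return True

    for code in sorted(CLASS_NAMES):
        lo, hi = sizes[code]
        for _ in range(int(counts[code])):
            h = int(rng.integers(lo, hi + 1))
            w = int(rng.integers(lo, hi + 1))
            # shrink towards the minimum size before giving up
            while not place(code, h, w):
                if h <= lo and w <= lo:
                    raise PlacementError(
                        f"could not place field {len(polygons) + 1} "
                        f"(class {CLASS_NAMES[code]}) in a {rows}x{cols} extent"
                    )
                h, w = max(h - 1, lo), max(w - 1, lo)
    return LandCoverMap(labels=labels, polygons=polygons, background=bg)


# --------------------------------------------------------------------------
# SAR scattering profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringParams:
    """Per-class, per-date generative scattering state."""

    mv: float  # volume (unpolarized) power, linear units, >= 0
    ms: float  # polarized power, linear units, >= 0
    alpha_deg: float  # polarized-component angle, [0, 90] deg
    delta_deg: float = 0.0  # polarized-component phase, [-180, 180] deg

    def __post_init__(self) -> None:
        if self.mv < 0 or self.ms < 0:
            raise ValueError("powers must be non-negative")
        if not 0.0 <= self.alpha_deg <= 90.0:
            raise ValueError("alpha must be in [0, 90] degrees")
        if not -180.0 <= self.delta_deg <= 180.0:
            raise ValueError("delta must be in [-180, 180] degrees")

    def stokes(self) -> np.ndarray:
        """True Stokes vector mv*sv + ms*sp (satisfies s1 >= |s_pol|)."""
        two_a = np.radians(2.0 * self.alpha_deg)
        d = np.radians(self.delta_deg)
        sv = np.array([1.0, 0.5, 0.0, 0.0])
        sp = np.array(
            [1.0, np.cos(two_a), np.sin(two_a) * np.cos(d), np.sin(two_a) * np.sin(d)]
        )
        return self.mv * sv + self.ms * sp

    def covariance(self) -> np.ndarray:
        """2x2 Hermitian covariance equivalent of the true Stokes vector."""
        s = self.stokes()
        sr = StokesRaster(*(np.array([v]) for v in s))
        c2 = stokes_to_c2(sr)
        return np.array(
            [[c2.c11[0], c2.c12[0]], [np.conj(c2.c12[0]), c2.c22[0]]], dtype=complex
        )


@dataclass
class CropScatteringProfile:
    """Generative SAR parameters: (class, date) -> ScatteringParams.

    ``dispersion`` is the per-class relative standard deviation of a
    lognormal per-pixel power scaling (unit mean) modelling within-class
    variability; ``looks`` is the default number of single-look samples
    averaged per pixel.
    """

    params: dict[tuple[int, str], ScatteringParams]
    looks: int = 1
    dispersion: dict[int, float] = dc_field(default_factory=dict)

    def get(self, class_code: int, date: str) -> ScatteringParams:
        try:
            return self.params[(class_code, date)]
        except KeyError:
            raise KeyError(
                f"no scattering parameters for class "
                f"{CLASS_NAMES.get(class_code, class_code)} on {date}"
            ) from None

    @property
    def dates(self) -> list[str]:
        return sorted({d for _, d in self.params})


def _bump(doy: float, base: float, amp: float, peak: float, width: float) -> float:
    """Gaussian phenology bump over day-of-year."""
    return base + amp * float(np.exp(-0.5 * ((doy - peak) / width) ** 2))


#: Per-class phenology of the SAR scattering state:
#: (mv base, amp, peak doy, width), (ms base, amp, peak doy, width),
#: alpha (deg), delta (deg).
_SAR_PHENOLOGY: dict[str, tuple] = {
    "rice":      ((0.010, 0.35, 230, 50), (0.040, 0.10, 130, 60), 8.0, 0.0),
    "soybean":   ((0.020, 0.25, 200, 45), (0.050, 0.04, 110, 50), 18.0, 0.0),
    "ramie":     ((0.100, 0.20, 190, 80), (0.050, 0.02, 150, 80), 25.0, 0.0),
    "corn":      ((0.020, 0.40, 215, 45), (0.060, 0.10, 250, 40), 35.0, 60.0),
    "grassland": ((0.120, 0.06, 180, 90), (0.030, 0.00, 180, 90), 15.0, 0.0),
    "water":     ((0.004, 0.00, 180, 90), (0.030, 0.00, 180, 90), 3.0, 0.0),
    "forest":    ((0.450, 0.08, 200, 90), (0.080, 0.00, 180, 90), 30.0, 0.0),
    "building":  ((0.080, 0.00, 180, 90), (0.700, 0.00, 180, 90), 75.0, 120.0),
}


def default_scattering_profile(
    dates: tuple[str, ...] = SAR_DATES,
    looks: int = 1,
    dispersion: float = 0.10,
) -> CropScatteringProfile:
    """Season-long scattering trajectories for the 8 classes."""
    params: dict[tuple[int, str], ScatteringParams] = {}
    for name, (mv_p, ms_p, alpha, delta) in _SAR_PHENOLOGY.items():
        code = CLASS_CODES[name]
        for date in dates:
            doy = day_of_year(date)
            params[(code, date)] = ScatteringParams(
                mv=_bump(doy, *mv_p),
                ms=_bump(doy, *ms_p),
                alpha_deg=alpha,
                delta_deg=delta,
            )
    return CropScatteringProfile(
        params=params,
        looks=looks,
        dispersion={code: dispersion for code in CLASS_NAMES},
    )


def simulate_sar_scene(
    lcmap: LandCoverMap,
    profile: CropScatteringProfile,
    date: str,
    looks: int | None = None,
    seed: int = 0,
) -> C2Raster:
    """Render one speckled dual-pol covariance scene.

    Per pixel, the true covariance is the covariance equivalent of
    ``mv*sv + ms*sp`` for the pixel's class (optionally scaled by a unit-
    mean lognormal within-class dispersion), and the returned raster is
    the average of ``looks`` independent single-look outer products of
    CN(0, C_true) channel pairs, so its expectation is C_true.
    """
    L = int(profile.looks if looks is None else looks)
    if L < 1:
        raise ValueError("looks must be >= 1")
    rows, cols = lcmap.shape
    rng = np.random.default_rng(seed)

    c11 = np.zeros((rows, cols))
    c22 = np.zeros((rows, cols))
    c12 = np.zeros((rows, cols), dtype=complex)

    for code in lcmap.present_classes():
        par = profile.get(code, date)  # raises for a missing class/date
        cov = par.covariance()
        mask = lcmap.labels == code
        n = int(mask.sum())
        if n == 0:
            continue
        # matrix square root via eigen-decomposition (robust for singular C)
        w, v = np.linalg.eigh(cov)
        a_mat = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
        z = (
            rng.standard_normal((n, L, 2)) + 1j * rng.standard_normal((n, L, 2))
        ) / np.sqrt(2.0)
        x = z @ a_mat.T  # rows of x have covariance A A^H = C
        sigma = float(profile.dispersion.get(code, 0.0))
        if sigma > 0:
            # lognormal with unit mean and relative sd ~ sigma
            s2 = np.log1p(sigma**2)
            scale = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)
            x = x * np.sqrt(scale)[:, None, None]
        c11[mask] = np.mean(np.abs(x[:, :, 0]) ** 2, axis=1)
        c22[mask] = np.mean(np.abs(x[:, :, 1]) ** 2, axis=1)
        c12[mask] = np.mean(x[:, :, 0] * np.conj(x[:, :, 1]), axis=1)

    return C2Raster(c11=c11, c22=c22, c12=c12, date=date, looks=float(L))


# --------------------------------------------------------------------------
# optical reflectance profiles
# --------------------------------------------------------------------------

#: End-member reflectance spectra over the 12 bands
#: (B1 B2 B3 B4 B5 B6 B7 B8 B8A B9 B11 B12).
_VEG = np.array([0.03, 0.04, 0.08, 0.04, 0.15, 0.35, 0.42, 0.45, 0.46, 0.46, 0.22, 0.10])
_SOIL = np.array([0.08, 0.10, 0.13, 0.16, 0.18, 0.20, 0.22, 0.24, 0.25, 0.26, 0.30, 0.28])
_WATER = np.array([0.08, 0.07, 0.05, 0.03, 0.02, 0.015, 0.012, 0.010, 0.010, 0.008, 0.004, 0.003])
_URBAN = np.array([0.18, 0.20, 0.22, 0.24, 0.25, 0.26, 0.27, 0.28, 0.28, 0.27, 0.26, 0.25])

#: Per-class fractional-vegetation phenology (base, amp, peak doy, width)
#: and background spectrum.
_OPTICAL_PHENOLOGY: dict[str, tuple] = {
    "rice":      ((0.02, 0.93, 225, 45), 0.5 * _WATER + 0.5 * _SOIL),
    "soybean":   ((0.02, 0.88, 200, 40), _SOIL),
    "ramie":     ((0.35, 0.50, 190, 70), _SOIL),
    "corn":      ((0.02, 0.88, 210, 45), _SOIL),
    "grassland": ((0.50, 0.25, 180, 90), _SOIL),
    "water":     ((0.00, 0.00, 180, 90), _WATER),
    "forest":    ((0.85, 0.10, 200, 100), _SOIL),
    "building":  ((0.00, 0.00, 180, 90), _URBAN),
}


@dataclass
class CropReflectanceProfile:
    """Generative optical parameters: (class, date) -> 12-band means.

    ``noise_sd`` is the additive Gaussian reflectance noise;
    ``cloud_fraction`` maps a date to the target fraction of the scene
    covered by cloud patches; ``cloud_reflectance`` is the bright,
    class-independent value clouds impose.
    """

    means: dict[tuple[int, str], np.ndarray]
    noise_sd: float = 0.02
    cloud_fraction: dict[str, float] = dc_field(default_factory=dict)
    cloud_reflectance: float = 0.85

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for date, f in self.cloud_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"cloud fraction for {date} outside [0, 1]")
        for key, m in self.means.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (len(OPTICAL_BAND_NAMES),):
                raise ValueError(f"means for {key} must have 12 bands")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError(f"means for {key} outside [0, 1]")
            self.means[key] = m

    def get(self, class_code: int, date: str) -> np.ndarray:
        try:
            return self.means[(class_code, date)]
        except KeyError:
            raise KeyError(
                f"no reflectance for class "
                f"{CLASS_NAMES.get(class_code, class_code)} on {date}"
            ) from None

    @property
    def dates(self) -> list[str]:
        return sorted({d for _, d in self.means})


def default_reflectance_profile(
    dates: tuple[str, ...] = OPTICAL_DATES,
    noise_sd: float = 0.02,
    cloud_fraction: dict[str, float] | None = None,
) -> CropReflectanceProfile:
    """Season-long 12-band reflectance trajectories for the 8 classes.

    Class means are linear mixtures of vegetation and background spectra
    driven by a fractional-cover phenology curve.  By default the last
    September date carries a 15% cloud fraction (below the 20% screen);
    all other dates are clear.
    """
    means: dict[tuple[int, str], np.ndarray] = {}
    for name, (fv_p, bg_spec) in _OPTICAL_PHENOLOGY.items():
        code = CLASS_CODES[name]
        for date in dates:
            fv = float(np.clip(_bump(day_of_year(date), *fv_p), 0.0, 1.0))
            means[(code, date)] = np.clip(fv * _VEG + (1 - fv) * bg_spec, 0.0, 1.0)
    if cloud_fraction is None:
        cloud_fraction = {d: 0.0 for d in dates}
        if "20240918" in dates:
            cloud_fraction["20240918"] = 0.15
    return CropReflectanceProfile(
        means=means, noise_sd=noise_sd, cloud_fraction=dict(cloud_fraction)
    )


def _cloud_mask(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous cloud patches covering approximately ``fraction``."""
    mask = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return mask
    if fraction >= 0.999:
        return np.ones(shape, dtype=bool)
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    max_r = max(3.0, min(rows, cols) / 12.0)
    for _ in range(100_000):
        if mask.mean() >= fraction:
            break
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        rad = rng.uniform(2.0, max_r)
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
    return mask


def simulate_optical_scene(
    lcmap: LandCoverMap,
    profile: CropReflectanceProfile,
    date: str,
    seed: int = 0,
    cloud_fraction: float | None = None,
) -> OpticalScene:
    """Render one 12-band optical scene with noise and optional clouds.

    Reflectance is synthesised on the 10 m grid (class mean + Gaussian
    noise, clipped to [0, 1]; cloud pixels overwritten by the bright cloud
    value), then 20 m / 60 m bands are degraded to their native resolution
    by block averaging, so that grid resampling is exercised downstream.
    """
    frac = profile.cloud_fraction.get(date, 0.0) if cloud_fraction is None else cloud_fraction
    if not 0.0 <= frac <= 1.0:
        raise ValueError("cloud fraction must be in [0, 1]")
    rows, cols = lcmap.shape
    rng = np.random.default_rng(seed)

    # per-class mean stack on the 10 m grid
    mean_stack = np.zeros((rows, cols, len(OPTICAL_BAND_NAMES)))
    for code in lcmap.present_classes():
        mean_stack[lcmap.labels == code] = profile.get(code, date)

    noise = (
        rng.normal(0.0, profile.noise_sd, mean_stack.shape)
        if profile.noise_sd > 0
        else 0.0
    )
    stack = np.clip(mean_stack + noise, 0.0, 1.0)

    mask = _cloud_mask((rows, cols), frac, rng)
    if mask.any():
        cloud_vals = np.clip(
            profile.cloud_reflectance
            + rng.normal(0.0, 0.03, (int(mask.sum()), stack.shape[-1])),
            0.0,
            1.0,
        )
        stack[mask] = cloud_vals

    bands: dict[str, np.ndarray] = {}
    for i, name in enumerate(OPTICAL_BAND_NAMES):
        native = BAND_RESOLUTION[name]
        band = stack[:, :, i]
        if native > 10:
            f = native // 10
            h2, w2 = (rows // f) * f, (cols // f) * f
            band = (
                band[:h2, :w2]
                .reshape(h2 // f, f, w2 // f, f)
                .mean(axis=(1, 3))
            )
        bands[name] = band
    return OpticalScene(
        bands=bands,
        grid_shape=(rows, cols),
        date=date,
        cloud_mask=mask,
        resolutions=dict(BAND_RESOLUTION),
    )


# --------------------------------------------------------------------------
# sample polygons
# --------------------------------------------------------------------------

def sample_polygons(
    lcmap: LandCoverMap,
    imbalance: dict | None = None,
    seed: int = 0,
) -> SamplePolygons:
    """Select class-labeled sample polygons from the map's fields.

    With ``imbalance=None`` every field polygon is returned.  Otherwise
    ``imbalance`` maps class (code or name) to a relative pixel-count
    target (e.g. ``{"rice": 70, "corn": 1}``); polygons are selected —
    and the last one per class cropped to a sub-rectangle — so that
    per-class pixel counts approximate the requested ratios, anchored at
    the most pixel-constrained class.  Classes absent from ``imbalance``
    keep all their polygons.
    """
    grid = lcmap.shape
    if not lcmap.polygons:
        return SamplePolygons(polygons=[], grid_shape=grid)
    if imbalance is None:
        return SamplePolygons(polygons=list(lcmap.polygons), grid_shape=grid)

    targets: dict[int, float] = {}
    for key, val in imbalance.items():
        code = CLASS_CODES[key] if isinstance(key, str) else int(key)
        if val <= 0:
            raise ValueError("imbalance weights must be positive")
        targets[code] = float(val)

    rng = np.random.default_rng(seed)
    by_class: dict[int, list[FieldPolygon]] = {}
    for p in lcmap.polygons:
        by_class.setdefault(p.class_code, []).append(p)

    available = {
        code: sum(p.pixel_count(grid) for p in polys)
        for code, polys in by_class.items()
    }
    # binding constraint: the class that runs out of pixels first
    scale = min(
        available[code] / weight
        for code, weight in targets.items()
        if code in available
    )

    selected: list[FieldPolygon] = []
    for code in sorted(by_class):
        polys = list(by_class[code])
        if code not in targets:
            selected.extend(polys)
            continue
        budget = scale * targets[code]
        order = rng.permutation(len(polys))
        count = 0
        for idx in order:
            poly = polys[idx]
            n = poly.pixel_count(grid)
            remaining = budget - count
            if remaining < 1:
                break
            if n <= remaining:
                selected.append(poly)
                count += n
            else:
                cropped = _crop_to_area(poly, remaining)
                if cropped is not None:
                    selected.append(cropped)
                    count += cropped.pixel_count(grid)
                break
    return SamplePolygons(polygons=selected, grid_shape=grid)


def _crop_to_area(poly: FieldPolygon, target_px: float) -> FieldPolygon | None:
    """Sub-rectangle of a rectangular field with ~``target_px`` pixels."""
    minx, miny, maxx, maxy = poly.polygon.bounds
    h = int(round(maxy - miny))
    w = int(round(maxx - minx))
    if h < 1 or w < 1 or target_px < 1:
        return None
    best = None
    for r in range(1, h + 1):
        c = int(np.clip(round(target_px / r), 1, w))
        err = abs(r * c - target_px)
        if best is None or err < best[0]:
            best = (err, r, c)
    _, r, c = best
    return FieldPolygon(
        poly.class_code, box(minx, miny, minx + c, miny + r)
    )
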