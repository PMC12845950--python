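"""Polarimetric decomposition of the dual-pol covariance.

Two decompositions are computed per date:

**Eigenvalue decomposition (entropy / anisotropy / alpha).**  The 2x2
Hermitian covariance has real eigenvalues l1 >= l2 >= 0 with
pseudo-probabilities P_i = l_i / (l1 + l2).  From these,

    H     = -sum_i P_i log2 P_i          (scattering randomness, [0, 1])
    A     = (l1 - l2) / (l1 + l2)        (eigenvalue imbalance, [0, 1])
    alpha = P1 a1 + P2 a2                (mean scattering angle, [0, 90] deg)

where a_i = arccos |u_i[0]| is the pseudo-alpha of eigenvector u_i — the
angle of the eigenvector away from the first (VV) channel.  With two
eigenvalues the base-2 logarithm normalises H to [0, 1], and the anisotropy
is the only well-defined two-eigenvalue form.

**Model-based (volume + polarized) decomposition.**  The Stokes vector is
modelled as an unpolarized random-dipole-cloud volume term plus a fully
polarized term,

    s = mv * sv + ms * sp,   sv = [1, 1/2, 0, 0],
    sp = [1, cos 2a, sin 2a cos d, sin 2a sin d],

the noise term being assumed removed by speckle filtering.  Because sp is
fully polarized it is null for the Minkowski-like form G = diag(1,-1,-1,-1)
(sp' G sp = 0), so mv solves the quadratic

    a mv^2 + b mv + c = 0,
    a = sv' G sv = 3/4,  b = -2 s' G sv = -2 (s1 - s2/2),
    c = s' G s = s1^2 - s2^2 - s3^2 - s4^2,

and energy conservation (0 <= mv <= s1) selects the physical root.  The
polarized power is the remainder ms = s1 - mv.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntFlag

import numpy as np

from .cube import BandMeta, FeatureCube
from .legend import SAR_FEATURES
from .sar import C2Raster, StokesRaster, intensity_db

__all__ = [
    "VOLUME_STOKES",
    "STOKES_METRIC",
    "volume_quadratic_coefficient",
    "EigenResult",
    "HAAlphaRaster",
    "ModelDecompRaster",
    "DecompFlags",
    "eigen_decompose",
    "entropy_anisotropy_alpha",
    "model_based_decompose",
    "sar_feature_vector",
]

#: Unpolarized Stokes signature of a random dipole cloud, VV channel first
#: (the 3:1 VV:VH power ratio of the dipole cloud gives s2/s1 = +1/2).
VOLUME_STOKES: np.ndarray = np.array([1.0, 0.5, 0.0, 0.0])

#: Quadratic form under which fully polarized Stokes vectors are null.
STOKES_METRIC: np.ndarray = np.diag([1.0, -1.0, -1.0, -1.0])


def volume_quadratic_coefficient(sv: np.ndarray | None = None) -> float:
    """Leading coefficient ``a = sv' G sv`` of the volume-power quadratic.

    For the default random-dipole volume signature this is exactly 3/4.
    """
    v = VOLUME_STOKES if sv is None else np.asarray(sv, dtype=float)
    return float(v @ STOKES_METRIC @ v)


class DecompFlags(IntFlag):
    """Per-pixel diagnostic flags of the model-based decomposition."""

    OK = 0
    NEGATIVE_DISCRIMINANT = 1
    ROOT_CLAMPED = 2
    NON_FINITE = 4
    ZERO_POWER = 8


@dataclass
class EigenResult:
    """Closed-form eigen-analysis of the 2x2 covariance, per pixel."""

    l1: np.ndarray
    l2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    alpha1: np.ndarray  # degrees
    alpha2: np.ndarray  # degrees
    degenerate: np.ndarray  # zero-span or non-finite pixels
    date: str | None = None


@dataclass
class HAAlphaRaster:
    """Entropy, anisotropy and mean alpha angle rasters."""

    h: np.ndarray
    a: np.ndarray
    alpha: np.ndarray  # degrees
    date: str | None = None


@dataclass
class ModelDecompRaster:
    """Volume power mv and polarized power ms rasters, with flags."""

    mv: np.ndarray
    ms: np.ndarray
    flags: np.ndarray  # DecompFlags bitmask per pixel
    date: str | None = None


def eigen_decompose(c2: C2Raster) -> EigenResult:
    """Exact eigenvalues/eigenvectors of the 2x2 Hermitian covariance.

    Eigenvalues are sorted descending and clipped at zero (they are real
    non-negative for a PSD matrix up to round-off).  Pixels with zero span
    or non-finite input are flagged degenerate and given P = (1/2, 1/2),
    alpha_i = 0.
    """
    c11, c22, c12 = c2.c11, c2.c22, c2.c12
    span = c11 + c22
    finite = np.isfinite(c11) & np.isfinite(c22) & np.isfinite(c12)
    degenerate = ~finite | (span <= 0)

    half_tr = 0.5 * np.where(finite, span, 0.0)
    # eigenvalue offset: sqrt of ((C11-C22)/2)^2 + |C12|^2
    with np.errstate(invalid="ignore"):
        radius = np.hypot(
            0.5 * np.where(finite, c11 - c22, 0.0),
            np.abs(np.where(finite, c12, 0.0)),
        )
    l1 = np.maximum(half_tr + radius, 0.0)
    l2 = np.maximum(half_tr - radius, 0.0)

    total = l1 + l2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(total > 0, l1 / np.where(total > 0, total, 1.0), 0.5)
    p1 = np.where(degenerate, 0.5, p1)
    p2 = 1.0 - p1

    # |first component| of each unit eigenvector.  For C12 != 0 the
    # (unnormalised) eigenvector of l_i is [C12, l_i - C11]; for the
    # diagonal case it is e1 or e2 depending on which diagonal dominates.
    abs_c12 = np.abs(np.where(finite, c12, 0.0))
    off_diag = abs_c12 > 1e-30 * np.maximum(span, 1.0)

    def first_component(l: np.ndarray, top_is_e1: np.ndarray) -> np.ndarray:
        num = abs_c12
        den = np.hypot(abs_c12, np.abs(l - np.where(finite, c11, 0.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
        return np.where(off_diag, frac, np.where(top_is_e1, 1.0, 0.0))

    c11_dominant = np.where(finite, c11, 0.0) >= np.where(finite, c22, 0.0)
    u1_first = first_component(l1, c11_dominant)
    u2_first = first_component(l2, ~c11_dominant)

    alpha1 = np.degrees(np.arccos(np.clip(u1_first, 0.0, 1.0)))
    alpha2 = np.degrees(np.arccos(np.clip(u2_first, 0.0, 1.0)))
    alpha1 = np.where(degenerate, 0.0, alpha1)
    alpha2 = np.where(degenerate, 0.0, alpha2)

    return EigenResult(
        l1=l1, l2=l2, p1=p1, p2=p2,
        alpha1=alpha1, alpha2=alpha2,
        degenerate=degenerate, date=c2.date,
    )


def entropy_anisotropy_alpha(e: EigenResult) -> HAAlphaRaster:
    """H / A / alpha from the eigen-analysis (formulas in module docstring)."""

    def plogp(p: np.ndarray) -> np.ndarray:
        # 0 log 0 := 0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)

    h = np.clip(-(plogp(e.p1) + plogp(e.p2)), 0.0, 1.0)

    total = e.l1 + e.l2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(total > 0, (e.l1 - e.l2) / np.where(total > 0, total, 1.0), 0.0)
    a = np.clip(a, 0.0, 1.0)

    alpha = np.clip(e.p1 * e.alpha1 + e.p2 * e.alpha2, 0.0, 90.0)
    # degenerate pixels: maximum-entropy convention
    h = np.where(e.degenerate, 1.0, h)
    a = np.where(e.degenerate, 0.0, a)
    alpha = np.where(e.degenerate, 0.0, alpha)
    return HAAlphaRaster(h=h, a=a, alpha=alpha, date=e.date)


def model_based_decompose(s: StokesRaster) -> ModelDecompRaster:
    """Volume / polarized power retrieval from the Stokes raster.

    Solves ``a mv^2 + b mv + c = 0`` per pixel (coefficients in the module
    docstring) and selects the root obeying energy conservation
    ``0 <= mv <= s1``; ``ms = s1 - mv``.  Degenerate cases:

    * both roots admissible (double root / numerical near-tie): the smaller
      root is taken;
    * negative discriminant (speckle noise pushed the observable outside
      the model manifold): the vertex ``-b/(2a)`` is taken, clipped to
      ``[0, s1]``, and flagged;
    * no root in ``[0, s1]``: the nearest root is clipped in and flagged.
    """
    s1, s2, s3, s4 = s.s1, s.s2, s.s3, s.s4
    finite = np.isfinite(s1) & np.isfinite(s2) & np.isfinite(s3) & np.isfinite(s4)
    s1c = np.where(finite, s1, 0.0)

    a = volume_quadratic_coefficient()
    b = -2.0 * (np.where(finite, s1, 0.0) - 0.5 * np.where(finite, s2, 0.0))
    c = np.where(
        finite, s1**2 - s2**2 - s3**2 - s4**2, 0.0
    )

    flags = np.zeros(s1.shape, dtype=np.int16)
    flags[~finite] |= DecompFlags.NON_FINITE

    disc = b**2 - 4.0 * a * c
    neg_disc = disc < 0
    flags[neg_disc & finite] |= DecompFlags.NEGATIVE_DISCRIMINANT
    sqrt_disc = np.sqrt(np.maximum(disc, 0.0))

    r_lo = (-b - sqrt_disc) / (2.0 * a)
    r_hi = (-b + sqrt_disc) / (2.0 * a)
    vertex = -b / (2.0 * a)

    # admissibility with a span-scaled tolerance
    tol = 1e-9 * np.maximum(s1c, 1e-30)
    lo_ok = (r_lo >= -tol) & (r_lo <= s1c + tol)
    hi_ok = (r_hi >= -tol) & (r_hi <= s1c + tol)

    mv = np.where(lo_ok, r_lo, np.where(hi_ok, r_hi, r_lo))
    # no admissible root: take whichever root is nearest to [0, s1]
    none_ok = ~(lo_ok | hi_ok) & ~neg_disc
    if np.any(none_ok):
        d_lo = np.maximum(r_lo - s1c, -r_lo)
        d_hi = np.maximum(r_hi - s1c, -r_hi)
        mv = np.where(none_ok, np.where(d_lo <= d_hi, r_lo, r_hi), mv)
        flags[none_ok] |= DecompFlags.ROOT_CLAMPED
    mv = np.where(neg_disc, vertex, mv)

    clipped = (mv < 0) | (mv > s1c)
    flags[clipped & finite & ~none_ok & ~neg_disc] |= DecompFlags.ROOT_CLAMPED
    mv = np.clip(mv, 0.0, s1c)

    zero = s1c <= 0
    mv = np.where(zero, 0.0, mv)
    flags[zero & finite] |= DecompFlags.ZERO_POWER

    ms = s1c - mv
    return ModelDecompRaster(mv=mv, ms=ms, flags=flags, date=s.date)


def sar_feature_vector(
    c2: C2Raster,
    haa: HAAlphaRaster,
    md: ModelDecompRaster,
    features: tuple[str, ...] = SAR_FEATURES,
) -> FeatureCube:
    """Assemble the per-date SAR feature raster.

    Default band order is ``[VV_dB, VH_dB, H, A, alpha, mv, ms]``, each band
    tagged with the acquisition date; stacking 12 dates downstream yields
    the 84-band SAR feature set.
    """
    if not (c2.shape == haa.h.shape == md.mv.shape):
        raise ValueError("feature rasters must share one grid")
    if not (c2.date == haa.date == md.date):
        raise ValueError("feature rasters must share one acquisition date")
    vv_db, vh_db = intensity_db(c2)
    available = {
        "VV_dB": vv_db, "VH_dB": vh_db,
        "H": haa.h, "A": haa.a, "alpha": haa.alpha,
        "mv": md.mv, "ms": md.ms,
    }
    unknown = [f for f in features if f not in available]
    if unknown:
        raise ValueError(f"unknown SAR features: {unknown}")
    values = np.stack([available[f] for f in features], axis=-1)
    meta = [BandMeta(sensor="SAR", date=c2.date or "", feature=f) for f in features]
    return FeatureCube(values=values, meta=meta)
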