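"""Dual-pol covariance (C2) construction and conditioning.

The per-pixel observable of a dual-pol (VV, VH) SAR is the 2x2 Hermitian
covariance matrix

    C2 = [[ <|S_vv|^2>,        <S_vv S_vh*> ],
          [ <S_vh S_vv*>,      <|S_vh|^2>   ]]

stored here as three rasters (C11, C22 real; C12 complex).  Multi-looking
and boxcar filtering average C2 element-wise, which reduces speckle while
preserving positive semi-definiteness.  The equivalent Stokes-vector view

    s1 = C11 + C22,  s2 = C11 - C22,  s3 = 2 Re C12,  s4 = -2 Im C12

is the input of the model-based decomposition; the convention above is the
one the scene simulator inverts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ComplexDualPolImage",
    "C2Raster",
    "StokesRaster",
    "build_c2",
    "multilook",
    "boxcar_filter",
    "c2_to_stokes",
    "stokes_to_c2",
    "intensity_db",
]

#: dB floor, linear power units; below any simulated signal.
DB_FLOOR: float = 1e-10


@dataclass
class ComplexDualPolImage:
    """Co-registered complex VV / VH channel pair for one acquisition."""

    s_vv: np.ndarray
    s_vh: np.ndarray
    date: str | None = None
    pixel_size: float = 10.0

    def __post_init__(self) -> None:
        self.s_vv = np.asarray(self.s_vv, dtype=complex)
        self.s_vh = np.asarray(self.s_vh, dtype=complex)
        if self.s_vv.shape != self.s_vh.shape:
            raise ValueError(
                f"channel shapes differ: {self.s_vv.shape} vs {self.s_vh.shape}"
            )


@dataclass
class C2Raster:
    """Per-pixel 2x2 Hermitian covariance of the (VV, VH) channel pair."""

    c11: np.ndarray
    c22: np.ndarray
    c12: np.ndarray
    date: str | None = None
    looks: float = 1.0

    def __post_init__(self) -> None:
        self.c11 = np.asarray(self.c11, dtype=float)
        self.c22 = np.asarray(self.c22, dtype=float)
        self.c12 = np.asarray(self.c12, dtype=complex)
        if not (self.c11.shape == self.c22.shape == self.c12.shape):
            raise ValueError("C2 element rasters must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.c11.shape

    def total_power(self) -> np.ndarray:
        """Span C11 + C22 (equals Stokes s1)."""
        return self.c11 + self.c22

    def is_psd(self, rtol: float = 1e-9) -> np.ndarray:
        """Per-pixel positive semi-definiteness check.

        Hermitian 2x2 with non-negative diagonal is PSD iff
        C11*C22 >= |C12|^2 (within a tolerance scaled by the span).
        """
        span = self.total_power()
        eps = rtol * np.maximum(span, 1.0) ** 2
        return (
            (self.c11 >= -rtol * np.maximum(span, 1.0))
            & (self.c22 >= -rtol * np.maximum(span, 1.0))
            & (self.c11 * self.c22 >= np.abs(self.c12) ** 2 - eps)
        )


@dataclass
class StokesRaster:
    """Per-pixel Stokes vector (s1..s4), linear power units."""

    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    s4: np.ndarray
    date: str | None = None

    def __post_init__(self) -> None:
        self.s1, self.s2, self.s3, self.s4 = (
            np.asarray(s, dtype=float) for s in (self.s1, self.s2, self.s3, self.s4)
        )
        shapes = {s.shape for s in (self.s1, self.s2, self.s3, self.s4)}
        if len(shapes) != 1:
            raise ValueError("Stokes component rasters must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s1.shape

    def degree_of_polarization(self) -> np.ndarray:
        pol = np.sqrt(self.s2**2 + self.s3**2 + self.s4**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.s1 > 0, pol / self.s1, 0.0)


def build_c2(image: ComplexDualPolImage) -> C2Raster:
    """Single-look covariance from a complex channel pair.

    C11 = |S_vv|^2, C22 = |S_vh|^2, C12 = S_vv * conj(S_vh); the result is
    rank-1 per pixel (C11*C22 == |C12|^2 exactly).
    """
    return C2Raster(
        c11=np.abs(image.s_vv) ** 2,
        c22=np.abs(image.s_vh) ** 2,
        c12=image.s_vv * np.conj(image.s_vh),
        date=image.date,
        looks=1.0,
    )


def multilook(c2: C2Raster, range_factor: int, azimuth_factor: int) -> C2Raster:
    """Block-average each C2 element over ``range_factor x azimuth_factor``
    windows (rows x cols), truncating partial blocks at the edges."""
    rf, af = int(range_factor), int(azimuth_factor)
    if rf < 1 or af < 1:
        raise ValueError("multilook factors must be >= 1")
    if rf == 1 and af == 1:
        return replace(c2)

    def block_mean(a: np.ndarray) -> np.ndarray:
        h, w = a.shape
        h2, w2 = (h // rf) * rf, (w // af) * af
        a = a[:h2, :w2]
        return a.reshape(h2 // rf, rf, w2 // af, af).mean(axis=(1, 3))

    return C2Raster(
        c11=block_mean(c2.c11),
        c22=block_mean(c2.c22),
        c12=block_mean(c2.c12),
        date=c2.date,
        looks=c2.looks * rf * af,
    )


def boxcar_filter(c2: C2Raster, window: int = 9) -> C2Raster:
    """Element-wise moving average over a ``window x window`` neighbourhood.

    Edges are handled by reflection padding so the output keeps the input
    size.  Averaging PSD matrices is PSD, so the covariance invariant is
    preserved; the looks-equivalent count is multiplied by ``window**2``
    (exact only in homogeneous areas).
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError("boxcar window must be a positive odd integer")
    if window == 1:
        return replace(c2)

    def smooth(a: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(a):
            return smooth(a.real) + 1j * smooth(a.imag)
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    return C2Raster(
        c11=smooth(c2.c11),
        c22=smooth(c2.c22),
        c12=smooth(c2.c12),
        date=c2.date,
        looks=c2.looks * window**2,
    )


def c2_to_stokes(c2: C2Raster) -> StokesRaster:
    """Stokes-vector view of the covariance (convention in module docstring)."""
    return StokesRaster(
        s1=c2.c11 + c2.c22,
        s2=c2.c11 - c2.c22,
        s3=2.0 * c2.c12.real,
        s4=-2.0 * c2.c12.imag,
        date=c2.date,
    )


def stokes_to_c2(s: StokesRaster, looks: float = 1.0) -> C2Raster:
    """Exact inverse of :func:`c2_to_stokes`."""
    return C2Raster(
        c11=0.5 * (s.s1 + s.s2),
        c22=0.5 * (s.s1 - s.s2),
        c12=0.5 * (s.s3 - 1j * s.s4),
        date=s.date,
        looks=looks,
    )


def intensity_db(
    c2: C2Raster, floor: float = DB_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Backscatter intensities in dB: ``10 log10(max(C11|C22, floor))``."""
    if floor <= 0:
        raise ValueError("dB floor must be positive")
    vv_db = 10.0 * np.log10(np.maximum(c2.c11, floor))
    vh_db = 10.0 * np.log10(np.maximum(c2.c22, floor))
    return vv_db, vh_db
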