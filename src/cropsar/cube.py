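"""Multi-temporal, multi-sensor feature cubes.

A :class:`FeatureCube` is a (rows, cols, bands) value array with an ordered
list of per-band metadata (sensor, acquisition date, feature name).  Cubes
from successive dates are stacked chronologically, optical and SAR cubes
are fused by band concatenation, and the chronological-prefix sub-cubes
drive the incremental temporal-stacking experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandMeta", "FeatureCube", "stack_temporal", "fuse", "prefix_combinations"]


@dataclass(frozen=True)
class BandMeta:
    """Identity of one cube band: which sensor, which date, which feature."""

    sensor: str  # "SAR" | "optical"
    date: str  # YYYYMMDD
    feature: str

    @property
    def name(self) -> str:
        return f"{self.date}_{self.feature}"


class FeatureCube:
    """Pixels x bands feature container on a shared grid.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Feature values.
    meta : list of BandMeta
        One entry per band, in band order; (sensor, date, feature) triples
        must be unique.
    """

    def __init__(self, values: np.ndarray, meta: list[BandMeta]):
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[:, :, np.newaxis]
        if values.ndim != 3:
            raise ValueError("cube values must have shape (rows, cols, bands)")
        if values.shape[-1] != len(meta):
            raise ValueError(
                f"band count {values.shape[-1]} != metadata length {len(meta)}"
            )
        if len(set(meta)) != len(meta):
            raise ValueError("duplicate (sensor, date, feature) band metadata")
        self.values = values
        self.meta = list(meta)

    # -- basic introspection -------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[-1]

    @property
    def band_names(self) -> list[str]:
        return [m.name for m in self.meta]

    @property
    def dates(self) -> list[str]:
        """Unique acquisition dates, ascending."""
        return sorted({m.date for m in self.meta})

    @property
    def matrix(self) -> np.ndarray:
        """(n_pixels, n_bands) view for sample extraction / prediction."""
        return self.values.reshape(-1, self.n_bands)

    def __repr__(self) -> str:
        r, c = self.grid_shape
        return (
            f"FeatureCube({r}x{c} px, {self.n_bands} bands, "
            f"{len(self.dates)} dates)"
        )

    # -- selection -----------------------------------------------------------
    def select(
        self,
        dates: list[str] | None = None,
        sensors: list[str] | None = None,
        features: list[str] | None = None,
    ) -> "FeatureCube":
        """Sub-cube with bands matching every given filter, order preserved."""
        idx = [
            i
            for i, m in enumerate(self.meta)
            if (dates is None or m.date in dates)
            and (sensors is None or m.sensor in sensors)
            and (features is None or m.feature in features)
        ]
        if not idx:
            raise ValueError("selection matches no band")
        return FeatureCube(self.values[:, :, idx], [self.meta[i] for i in idx])


def stack_temporal(per_date_cubes: list[FeatureCube]) -> FeatureCube:
    """Stack per-date feature cubes into one multi-temporal cube.

    Bands are ordered by acquisition date ascending, keeping each date's
    internal feature order.  Duplicate (sensor, date, feature) triples or a
    grid mismatch are rejected.
    """
    if not per_date_cubes:
        raise ValueError("nothing to stack")
    grid = per_date_cubes[0].grid_shape
    if any(c.grid_shape != grid for c in per_date_cubes):
        raise ValueError("all cubes must share one grid")
    ordered = sorted(per_date_cubes, key=lambda c: min(m.date for m in c.meta))
    values = np.concatenate([c.values for c in ordered], axis=-1)
    meta: list[BandMeta] = []
    for c in ordered:
        meta.extend(c.meta)
    return FeatureCube(values, meta)  # uniqueness re-checked in constructor


def fuse(optical: FeatureCube, sar: FeatureCube) -> FeatureCube:
    """Concatenate optical bands then SAR bands on a shared grid.

    In the reference configuration (8 optical dates x 12 bands, 12 SAR
    dates x 7 features) this yields the 96 + 84 = 180-band fused cube.
    """
    if optical.n_bands == 0:
        return sar
    if sar.n_bands == 0:
        return optical
    if optical.grid_shape != sar.grid_shape:
        raise ValueError(
            f"grid mismatch: {optical.grid_shape} vs {sar.grid_shape}"
        )
    return FeatureCube(
        np.concatenate([optical.values, sar.values], axis=-1),
        optical.meta + sar.meta,
    )


def prefix_combinations(cube: FeatureCube) -> list[FeatureCube]:
    """Chronological-prefix sub-cubes.

    The k-th element contains exactly the bands of the first k acquisition
    dates (k = 1 .. n_dates); the last element equals the full cube.  This
    is the combination ladder of the incremental temporal experiments.
    """
    dates = cube.dates
    return [cube.select(dates=dates[: k + 1]) for k in range(len(dates))]
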