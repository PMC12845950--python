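"""Field polygons, polygon rasterization and labeled pixel samples.

Ground truth enters the pipeline as class-labeled polygons in pixel
coordinates (x = column, y = row; a pixel belongs to a polygon iff its
centre does).  :class:`SamplePolygons` is the polygon collection handed to
sample extraction; :class:`LabeledSamples` is the per-pixel design matrix
with an optional train/test split tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .legend import CLASS_NAMES

__all__ = [
    "FieldPolygon",
    "SamplePolygons",
    "LabeledSamples",
    "rasterize_polygon",
]


@dataclass(frozen=True)
class FieldPolygon:
    """One labeled field: class code + polygon in pixel coordinates."""

    class_code: int
    polygon: Polygon

    def pixel_indices(self, grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        return rasterize_polygon(self.polygon, grid_shape)

    def pixel_count(self, grid_shape: tuple[int, int]) -> int:
        return len(self.pixel_indices(grid_shape)[0])


def rasterize_polygon(
    poly: Polygon, grid_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of grid pixels whose centres fall inside ``poly``.

    Boundary convention: a centre exactly on the boundary counts as inside
    (covers the closed polygon), so an integer-cornered box from (c0, r0)
    to (c1, r1) covers exactly rows r0..r1-1 x cols c0..c1-1.
    """
    h, w = grid_shape
    minx, miny, maxx, maxy = poly.bounds
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)), h)
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)), w)
    if r1 <= r0 or c1 <= c0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x = cc.ravel() + 0.5
    y = rr.ravel() + 0.5
    inside = shapely.intersects_xy(poly, x, y)
    return rr.ravel()[inside], cc.ravel()[inside]


@dataclass
class SamplePolygons:
    """Class-labeled sample polygons with derived pixel memberships."""

    polygons: list[FieldPolygon]
    grid_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def class_codes(self) -> list[int]:
        return sorted({p.class_code for p in self.polygons})

    def pixel_counts(self) -> dict[int, int]:
        """Pixels per class over all polygons."""
        counts: dict[int, int] = {}
        for p in self.polygons:
            counts[p.class_code] = counts.get(p.class_code, 0) + p.pixel_count(
                self.grid_shape
            )
        return counts

    def summary(self) -> str:
        counts = self.pixel_counts()
        lines = ["class        polygons   pixels"]
        for code in self.class_codes:
            npoly = sum(1 for p in self.polygons if p.class_code == code)
            name = CLASS_NAMES.get(code, str(code))
            lines.append(f"{name:<12} {npoly:>8} {counts[code]:>8}")
        return "\n".join(lines)


@dataclass
class LabeledSamples:
    """Per-pixel samples: flat pixel ids, feature matrix, labels, split tag.

    ``split`` holds ``"train"`` / ``"test"`` per row once
    :func:`cropsar.classify.stratified_split` has run, else ``""``.
    """

    pixel_ids: np.ndarray  # flat indices into the grid
    x: np.ndarray  # (n, n_bands)
    y: np.ndarray  # (n,) class codes
    split: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))

    def __post_init__(self) -> None:
        if self.split.size == 0:
            self.split = np.full(len(self.y), "", dtype="U5")
        if not (len(self.pixel_ids) == len(self.x) == len(self.y) == len(self.split)):
            raise ValueError("sample arrays must share one length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def test_mask(self) -> np.ndarray:
        return self.split == "test"

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.y, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))
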