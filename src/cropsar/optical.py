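"""Conditioning of multi-band optical surface-reflectance scenes.

Scenes carry 12 reflectance bands at their native resolutions (10 / 20 /
60 m), a cloud mask on the 10 m grid and the scene cloud fraction.  The
pipeline resamples every band to the common 10 m grid (nearest-neighbour
by default), screens scenes against a cloud-fraction threshold (strict
"less than"), and emits per-date 12-band feature rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .cube import BandMeta, FeatureCube
from .legend import OPTICAL_BANDS, OPTICAL_BAND_NAMES

__all__ = [
    "OpticalScene",
    "resample_to_grid",
    "screen_scene",
    "optical_feature_vector",
    "CLOUD_SCREEN_THRESHOLD",
]

#: Maximum admissible scene cloud fraction (scenes at or above are rejected).
CLOUD_SCREEN_THRESHOLD: float = 0.20

#: Native band resolutions in metres.
BAND_RESOLUTION: dict[str, int] = dict(OPTICAL_BANDS)


@dataclass
class OpticalScene:
    """One acquisition of the 12-band surface-reflectance product.

    ``bands`` maps band name -> 2-D reflectance array at the resolution
    recorded in ``resolutions`` (metres per pixel); ``grid_shape`` is the
    extent of the common 10 m grid the scene belongs to.  The cloud mask
    lives on the 10 m grid.
    """

    bands: dict[str, np.ndarray]
    grid_shape: tuple[int, int]
    date: str | None = None
    cloud_mask: np.ndarray | None = None
    resolutions: dict[str, int] = field(default_factory=lambda: dict(BAND_RESOLUTION))

    def __post_init__(self) -> None:
        if self.cloud_mask is not None:
            self.cloud_mask = np.asarray(self.cloud_mask, dtype=bool)
            if self.cloud_mask.shape != tuple(self.grid_shape):
                raise ValueError("cloud mask must live on the 10 m grid")

    @property
    def cloud_fraction(self) -> float:
        if self.cloud_mask is None:
            return 0.0
        return float(self.cloud_mask.mean())

    @property
    def is_resampled(self) -> bool:
        return all(
            self.bands[name].shape == tuple(self.grid_shape) for name in self.bands
        )


def resample_to_grid(
    scene: OpticalScene,
    target_pixel_m: float = 10.0,
    method: str = "nearest",
) -> OpticalScene:
    """Bring every band onto the common 10 m grid.

    20 m / 60 m bands are upsampled (nearest-neighbour by default, which
    replicates each coarse pixel into an f x f block and preserves
    piecewise-constant class means exactly; ``method="bilinear"`` is
    available).  Bands already on the target grid are passed through
    untouched.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    out: dict[str, np.ndarray] = {}
    res: dict[str, int] = {}
    for name, arr in scene.bands.items():
        native = scene.resolutions.get(name, target_pixel_m)
        if native == target_pixel_m:
            if arr.shape != tuple(scene.grid_shape):
                raise ValueError(
                    f"band {name}: shape {arr.shape} inconsistent with the "
                    f"10 m grid {scene.grid_shape}"
                )
            out[name] = arr
        else:
            f = native / target_pixel_m
            # native extent may cover the grid by floor or round division
            ok = all(
                abs(arr.shape[i] * f - scene.grid_shape[i]) < f
                for i in (0, 1)
            )
            if not ok:
                raise ValueError(
                    f"band {name}: native shape {arr.shape} inconsistent with "
                    f"grid {scene.grid_shape} at {native} m"
                )
            if method == "nearest":
                fi = int(round(f))
                up = np.repeat(np.repeat(arr, fi, axis=0), fi, axis=1)
                if (
                    up.shape[0] < scene.grid_shape[0]
                    or up.shape[1] < scene.grid_shape[1]
                ):  # non-divisible extent: replicate the last row/col
                    pr = scene.grid_shape[0] - up.shape[0]
                    pc = scene.grid_shape[1] - up.shape[1]
                    up = np.pad(up, ((0, max(pr, 0)), (0, max(pc, 0))),
                                mode="edge")
                up = up[: scene.grid_shape[0], : scene.grid_shape[1]]
            else:
                up = resize(arr, scene.grid_shape, order=1, mode="edge",
                            anti_aliasing=False)
            out[name] = up
        res[name] = int(target_pixel_m)
    return OpticalScene(
        bands=out,
        grid_shape=scene.grid_shape,
        date=scene.date,
        cloud_mask=scene.cloud_mask,
        resolutions=res,
    )


def screen_scene(
    scene: OpticalScene, max_cloud_fraction: float = CLOUD_SCREEN_THRESHOLD
) -> tuple[bool, float]:
    """Accept a scene iff its cloud fraction is strictly below the threshold.

    Returns ``(accepted, fraction)``.
    """
    frac = scene.cloud_fraction
    return bool(frac < max_cloud_fraction), frac


def optical_feature_vector(
    scene: OpticalScene, band_names: tuple[str, ...] = OPTICAL_BAND_NAMES
) -> FeatureCube:
    """Per-date 12-band feature raster in canonical band order.

    Requires a resampled scene; stacking 8 dates downstream yields the
    96-band optical feature set.
    """
    if not scene.is_resampled:
        raise ValueError("scene must be resampled to the common grid first")
    missing = [b for b in band_names if b not in scene.bands]
    if missing:
        raise ValueError(f"scene is missing bands: {missing}")
    values = np.stack([scene.bands[b] for b in band_names], axis=-1)
    meta = [
        BandMeta(sensor="optical", date=scene.date or "", feature=b)
        for b in band_names
    ]
    return FeatureCube(values=values, meta=meta)
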