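"""Raster, cube and polygon persistence.

Rasters are written as plain multi-band TIFF (band-interleaved, float32 or
int16) with a JSON sidecar (``<name>.json``) carrying band names, pixel
size and free-form attributes; covariance rasters use the 4-band layout
(C11, C22, Re C12, Im C12), Stokes rasters (s1..s4), feature cubes one
band per (sensor, date, feature).  Polygons are written as GeoJSON
FeatureCollections in pixel coordinates with ``class`` / ``class_name``
properties.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .cube import BandMeta, FeatureCube
from .legend import CLASS_NAMES
from .samples import FieldPolygon, SamplePolygons
from .sar import C2Raster, StokesRaster

__all__ = [
    "write_raster", "read_raster",
    "write_c2", "read_c2",
    "write_stokes", "read_stokes",
    "write_cube", "read_cube",
    "write_labels", "read_labels",
    "write_polygons", "read_polygons",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(
    path: str | Path,
    values: np.ndarray,
    band_names: list[str],
    attrs: dict | None = None,
) -> Path:
    """Write a (rows, cols[, bands]) array as multi-band TIFF + sidecar."""
    path = Path(path)
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, np.newaxis]
    if values.shape[-1] != len(band_names):
        raise ValueError("band_names length must match the band count")
    planar = np.moveaxis(values, -1, 0)  # bands first for TIFF pages
    tifffile.imwrite(path, planar, photometric="minisblack")
    meta = {
        "band_names": list(band_names),
        "dtype": str(values.dtype),
        "attrs": attrs or {},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    """Inverse of :func:`write_raster`; returns (values, band_names, attrs)."""
    path = Path(path)
    planar = tifffile.imread(path)
    if planar.ndim == 2:
        planar = planar[np.newaxis]
    values = np.moveaxis(planar, 0, -1)
    meta = json.loads(_sidecar(path).read_text())
    return values, meta["band_names"], meta.get("attrs", {})


# -- covariance / Stokes ----------------------------------------------------

def write_c2(path: str | Path, c2: C2Raster) -> Path:
    values = np.stack([c2.c11, c2.c22, c2.c12.real, c2.c12.imag], axis=-1)
    return write_raster(
        path, values.astype(np.float32),
        ["C11", "C22", "ReC12", "ImC12"],
        attrs={"date": c2.date, "looks": c2.looks},
    )


def read_c2(path: str | Path) -> C2Raster:
    values, names, attrs = read_raster(path)
    if names != ["C11", "C22", "ReC12", "ImC12"]:
        raise ValueError(f"{path} is not a C2 raster (bands {names})")
    v = values.astype(float)
    return C2Raster(
        c11=v[:, :, 0], c22=v[:, :, 1],
        c12=v[:, :, 2] + 1j * v[:, :, 3],
        date=attrs.get("date"), looks=float(attrs.get("looks", 1.0)),
    )


def write_stokes(path: str | Path, s: StokesRaster) -> Path:
    values = np.stack([s.s1, s.s2, s.s3, s.s4], axis=-1)
    return write_raster(
        path, values.astype(np.float32), ["s1", "s2", "s3", "s4"],
        attrs={"date": s.date},
    )


def read_stokes(path: str | Path) -> StokesRaster:
    values, names, attrs = read_raster(path)
    if names != ["s1", "s2", "s3", "s4"]:
        raise ValueError(f"{path} is not a Stokes raster (bands {names})")
    v = values.astype(float)
    return StokesRaster(
        s1=v[:, :, 0], s2=v[:, :, 1], s3=v[:, :, 2], s4=v[:, :, 3],
        date=attrs.get("date"),
    )


# -- feature cubes ----------------------------------------------------------

def write_cube(path: str | Path, cube: FeatureCube) -> Path:
    attrs = {"bands": [
        {"sensor": m.sensor, "date": m.date, "feature": m.feature}
        for m in cube.meta
    ]}
    return write_raster(
        path, cube.values.astype(np.float32), cube.band_names, attrs=attrs
    )


def read_cube(path: str | Path) -> FeatureCube:
    values, _, attrs = read_raster(path)
    meta = [BandMeta(**b) for b in attrs["bands"]]
    return FeatureCube(values.astype(float), meta)


# -- label maps -------------------------------------------------------------

def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    return write_raster(
        path, labels.astype(np.int16), ["class_code"],
        attrs={"legend": {str(k): v for k, v in CLASS_NAMES.items()}},
    )


def read_labels(path: str | Path) -> np.ndarray:
    values, names, _ = read_raster(path)
    if names != ["class_code"]:
        raise ValueError(f"{path} is not a label raster")
    return values[:, :, 0].astype(np.int16)


# -- polygons ---------------------------------------------------------------

def write_polygons(path: str | Path, polygons: SamplePolygons) -> Path:
    """GeoJSON FeatureCollection in pixel coordinates."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {
                "class": int(p.class_code),
                "class_name": CLASS_NAMES.get(p.class_code, str(p.class_code)),
            },
        }
        for p in polygons.polygons
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "grid_shape": list(polygons.grid_shape),
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_polygons(path: str | Path) -> SamplePolygons:
    doc = json.loads(Path(path).read_text())
    polys = [
        FieldPolygon(
            class_code=int(f["properties"]["class"]),
            polygon=shape(f["geometry"]),
        )
        for f in doc["features"]
    ]
    return SamplePolygons(polygons=polys, grid_shape=tuple(doc["grid_shape"]))
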