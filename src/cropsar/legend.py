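"""Class legend, acquisition calendars and band definitions.

The package targets an 8-class agricultural landscape (a paddy-rice growing
region with four crops plus four background land covers) observed by a
C-band dual-pol (VV/VH) SAR on 12 dates and a 12-band optical sensor on
8 dates across one growing season.
"""

from __future__ import annotations

import datetime

#: Integer class codes. Code 0 is reserved for "unlabeled".
CLASS_NAMES: dict[int, str] = {
    1: "rice",
    2: "soybean",
    3: "ramie",
    4: "corn",
    5: "grassland",
    6: "water",
    7: "forest",
    8: "building",
}

CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: Dual-pol SAR acquisition dates (YYYYMMDD), 12-day revisit, Feb-Sep.
SAR_DATES: tuple[str, ...] = (
    "20240228", "20240311", "20240323", "20240404", "20240416", "20240428",
    "20240522", "20240615", "20240814", "20240826", "20240907", "20240919",
)

#: Optical acquisition dates (YYYYMMDD) passing the cloud screen.
OPTICAL_DATES: tuple[str, ...] = (
    "20240112", "20240211", "20240312", "20240804",
    "20240809", "20240824", "20240908", "20240918",
)

#: The seven per-date SAR features fed to the classifier, in band order.
SAR_FEATURES: tuple[str, ...] = ("VV_dB", "VH_dB", "H", "A", "alpha", "mv", "ms")

#: SAR intensity-only feature subset.
SAR_INTENSITY_FEATURES: tuple[str, ...] = ("VV_dB", "VH_dB")

#: Optical band names and native resolutions (m) of the atmospherically
#: corrected surface-reflectance product (12 bands; the cirrus band has no
#: surface-reflectance counterpart and is absent).
OPTICAL_BANDS: tuple[tuple[str, int], ...] = (
    ("B1", 60), ("B2", 10), ("B3", 10), ("B4", 10),
    ("B5", 20), ("B6", 20), ("B7", 20), ("B8", 10),
    ("B8A", 20), ("B9", 60), ("B11", 20), ("B12", 20),
)

OPTICAL_BAND_NAMES: tuple[str, ...] = tuple(name for name, _ in OPTICAL_BANDS)

#: Optical dates retained by the best fusion strategy (January through the
#: late-August acquisition, dropping the two September scenes).
BEST_OPTICAL_DATES: tuple[str, ...] = OPTICAL_DATES[:6]

#: Default pixel size of the common analysis grid, metres.
PIXEL_SIZE_M: float = 10.0


def day_of_year(date: str) -> int:
    """Day-of-year (1..366) for a YYYYMMDD date string."""
    d = datetime.datetime.strptime(date, "%Y%m%d").date()
    return d.timetuple().tm_yday
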