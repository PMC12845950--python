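"""Published reference tables for validating the accuracy assessment.

These are the printed results of a multi-temporal SAR/optical crop
classification case study over an 8-class paddy-rice landscape: the
confusion matrix of the best fused classification (test partition) and
the per-class ground-truth sample sizes.  They serve as fixed numerical
inputs for cross-checking :mod:`cropsar.evaluate` — recomputing PA, UA,
OA and Kappa from the raw counts must reproduce the printed percentages
at two decimals (two printed cells are known last-digit misprints; see
docs/methods.md).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "REFERENCE_CLASS_ORDER",
    "REFERENCE_CONFUSION_COUNTS",
    "REFERENCE_SAMPLE_PIXELS",
]

#: Class order of the reference confusion matrix (codes of the legend).
REFERENCE_CLASS_ORDER: tuple[int, ...] = (1, 2, 3, 5, 6, 7, 4, 8)
# i.e. rice, soybean, ramie, grassland, water, forest, corn, building

#: 8x8 confusion counts; rows = predicted, columns = ground truth,
#: both in REFERENCE_CLASS_ORDER.
REFERENCE_CONFUSION_COUNTS: np.ndarray = np.array(
    [
        [10716, 22, 0, 221, 332, 0, 3, 38],
        [132, 1357, 0, 62, 0, 0, 33, 0],
        [0, 0, 793, 3, 23, 0, 0, 0],
        [89, 13, 0, 283, 6, 0, 0, 1],
        [251, 0, 0, 33, 13566, 351, 0, 13],
        [63, 2, 0, 71, 1, 1941, 0, 0],
        [17, 0, 0, 0, 0, 0, 145, 0],
        [2, 22, 0, 6, 0, 0, 0, 530],
    ],
    dtype=np.int64,
)

#: Ground-truth sample sizes per class: (training polygons, training
#: pixels, testing polygons, testing pixels).
REFERENCE_SAMPLE_PIXELS: dict[str, tuple[int, int, int, int]] = {
    "forest": (40, 5230, 2, 2292),
    "water": (506, 35374, 58, 13928),
    "soybean": (197, 3634, 54, 1416),
    "ramie": (55, 1917, 12, 793),
    "rice": (1028, 28215, 199, 11270),
    "grassland": (99, 1537, 41, 679),
    "building": (88, 942, 74, 582),
    "corn": (14, 403, 5, 181),
}
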