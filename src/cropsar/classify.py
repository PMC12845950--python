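"""Random-forest crop classification: sampling, split, model, experiments.

The modelling surface follows the model/results idiom: a
:class:`CropClassifier` is constructed from a feature cube plus labeled
sample polygons (or pre-extracted samples); :meth:`CropClassifier.fit`
returns a :class:`ClassificationResult` carrying the fitted ensemble, the
test-set confusion matrix, PA/UA/OA/Kappa, per-feature importances and a
``summary()`` table, with map prediction and the incremental temporal
experiments hanging off these objects.

Reference protocol: 150 trees; per-class stratified 7:3 pixel split
(round-half-up on the 70% train share, remainder to test); feature
importances summed across dates per feature name and max-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cube import FeatureCube, prefix_combinations
from .evaluate import AccuracyReport, ConfusionMatrix, accuracy_report, confusion_matrix
from .legend import CLASS_NAMES
from .samples import LabeledSamples, SamplePolygons

__all__ = [
    "extract_samples",
    "stratified_split",
    "CropClassifier",
    "ClassificationResult",
    "train_random_forest",
    "predict_map",
    "normalized_importance",
    "temporal_experiment",
]

N_TREES_DEFAULT = 150
TRAIN_FRACTION_DEFAULT = 0.7


def extract_samples(cube: FeatureCube, polygons: SamplePolygons) -> LabeledSamples:
    """One row per labeled pixel; pixels under no polygon are excluded.

    Polygons of different classes must not overlap (ambiguous labels are
    an error); duplicate coverage by same-class polygons is counted once.
    """
    grid = cube.grid_shape
    if tuple(polygons.grid_shape) != tuple(grid):
        raise ValueError(
            f"polygon grid {polygons.grid_shape} != cube grid {grid}"
        )
    label_of: dict[int, int] = {}
    for p in polygons.polygons:
        rr, cc = p.pixel_indices(grid)
        for pid in (rr * grid[1] + cc).tolist():
            prev = label_of.get(pid)
            if prev is not None and prev != p.class_code:
                raise ValueError(
                    f"overlapping polygons with different classes at pixel "
                    f"{divmod(pid, grid[1])}"
                )
            label_of[pid] = p.class_code
    if not label_of:
        raise ValueError("polygons cover no pixel of the cube grid")
    pixel_ids = np.array(sorted(label_of), dtype=np.int64)
    y = np.array([label_of[i] for i in pixel_ids], dtype=np.int16)
    x = cube.matrix[pixel_ids]
    return LabeledSamples(pixel_ids=pixel_ids, x=x, y=y)


def stratified_split(
    samples: LabeledSamples,
    train_fraction: float = TRAIN_FRACTION_DEFAULT,
    seed: int = 0,
) -> LabeledSamples:
    """Per-class random train/test split at the given train share.

    The per-class train count is round-half-up of ``train_fraction * n``
    (so 10 pixels split 7:3 and 403 split 282:121); the remainder is
    tagged test.  Deterministic under the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = np.full(len(samples), "", dtype="U5")
    for code in np.unique(samples.y):
        idx = np.flatnonzero(samples.y == code)
        if len(idx) < 2:
            raise ValueError(
                f"class {CLASS_NAMES.get(int(code), code)} has fewer than "
                "2 pixels; cannot split"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both partitions non-empty
        perm = rng.permutation(idx)
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    return LabeledSamples(
        pixel_ids=samples.pixel_ids, x=samples.x, y=samples.y, split=split
    )


def train_random_forest(
    samples: LabeledSamples,
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the reference ensemble on the train partition.

    Hyperparameters beyond the tree count follow the library defaults.
    """
    mask = samples.train_mask
    if not mask.any():
        raise ValueError("samples carry no train split; run stratified_split first")
    y_train = samples.y[mask]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training partition must contain at least 2 classes")
    model = RandomForestClassifier(
        n_estimators=int(n_trees), random_state=int(seed), n_jobs=1
    )
    model.fit(samples.x[mask], y_train)
    return model


def _align_matrix(cube: FeatureCube, band_names: list[str]) -> np.ndarray:
    """Cube matrix with columns realigned to the training band order."""
    have = {m.name: i for i, m in enumerate(cube.meta)}
    missing = [n for n in band_names if n not in have]
    extra = [n for n in have if n not in band_names]
    if missing or extra:
        raise ValueError(
            f"cube bands do not match training bands; missing={missing}, "
            f"extra={extra}"
        )
    order = [have[n] for n in band_names]
    return cube.matrix[:, order]


def predict_map(
    model: RandomForestClassifier,
    cube: FeatureCube,
    band_names: list[str],
) -> np.ndarray:
    """Per-pixel class-code raster; bands are realigned by name."""
    mat = _align_matrix(cube, band_names)
    return model.predict(mat).reshape(cube.grid_shape).astype(np.int16)


def normalized_importance(
    model: RandomForestClassifier,
    band_names: list[str],
) -> pd.DataFrame:
    """Impurity importances summed across dates per feature name, then
    divided by the maximum; descending.  Band names follow the
    ``<date>_<feature>`` pattern."""
    raw: dict[str, float] = {}
    for name, imp in zip(band_names, model.feature_importances_):
        feature = name.split("_", 1)[1] if "_" in name else name
        raw[feature] = raw.get(feature, 0.0) + float(imp)
    table = pd.DataFrame(
        {"raw_importance": pd.Series(raw).sort_values(ascending=False)}
    )
    peak = table["raw_importance"].max()
    table["normalized_importance"] = (
        table["raw_importance"] / peak if peak > 0 else 0.0
    )
    table.index.name = "feature"
    return table


class CropClassifier:
    """Random-forest crop classification model over a feature cube.

    Parameters
    ----------
    cube : FeatureCube
        Multi-temporal (optionally multi-sensor) feature stack.
    polygons : SamplePolygons, optional
        Labeled ground-truth polygons; samples are extracted on ``fit``.
    samples : LabeledSamples, optional
        Pre-extracted samples (alternative to ``polygons``).
    n_trees, train_fraction :
        Reference protocol defaults: 150 trees, 7:3 stratified pixel split.
    """

    def __init__(
        self,
        cube: FeatureCube,
        polygons: SamplePolygons | None = None,
        samples: LabeledSamples | None = None,
        n_trees: int = N_TREES_DEFAULT,
        train_fraction: float = TRAIN_FRACTION_DEFAULT,
    ):
        if (polygons is None) == (samples is None):
            raise ValueError("provide exactly one of polygons / samples")
        self.cube = cube
        self.polygons = polygons
        self._samples = samples
        self.n_trees = int(n_trees)
        self.train_fraction = float(train_fraction)

    def fit(self, seed: int = 0) -> "ClassificationResult":
        """Extract samples (if needed), split, train and evaluate."""
        samples = (
            self._samples
            if self._samples is not None
            else extract_samples(self.cube, self.polygons)
        )
        if not samples.train_mask.any():
            samples = stratified_split(samples, self.train_fraction, seed=seed)
        model = train_random_forest(samples, n_trees=self.n_trees, seed=seed)
        y_pred = model.predict(samples.x[samples.test_mask])
        y_true = samples.y[samples.test_mask]
        labels = sorted(np.unique(samples.y).tolist())
        cm = confusion_matrix(y_pred, y_true, labels=labels)
        return ClassificationResult(
            model=model,
            samples=samples,
            band_names=self.cube.band_names,
            confusion=cm,
            accuracy=accuracy_report(cm),
            seed=seed,
        )


@dataclass
class ClassificationResult:
    """Fitted ensemble plus its held-out evaluation."""

    model: RandomForestClassifier
    samples: LabeledSamples
    band_names: list[str]
    confusion: ConfusionMatrix
    accuracy: AccuracyReport
    seed: int

    @property
    def oa(self) -> float:
        return self.accuracy.oa

    @property
    def kappa(self) -> float:
        return self.accuracy.kappa

    def importance(self) -> pd.DataFrame:
        """Max-normalized per-feature importance, aggregated across dates."""
        return normalized_importance(self.model, self.band_names)

    def predict_map(self, cube: FeatureCube) -> np.ndarray:
        """Classify every pixel of a cube with matching band metadata."""
        return predict_map(self.model, cube, self.band_names)

    def summary(self) -> str:
        n_train = int(self.samples.train_mask.sum())
        n_test = int(self.samples.test_mask.sum())
        head = (
            f"Random-forest crop classification "
            f"({self.model.n_estimators} trees, seed {self.seed})\n"
            f"bands: {len(self.band_names)}   train px: {n_train}   "
            f"test px: {n_test}\n"
        )
        return head + self.accuracy.summary()

    def plot_importance(self, ax=None):
        """Horizontal bar chart of the normalized feature importances."""
        import matplotlib.pyplot as plt

        table = self.importance()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        table["normalized_importance"][::-1].plot.barh(ax=ax)
        ax.set_xlabel("normalized importance")
        return ax


def temporal_experiment(
    cube: FeatureCube,
    polygons: SamplePolygons,
    seed: int = 0,
    n_trees: int = N_TREES_DEFAULT,
    train_fraction: float = TRAIN_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Incremental temporal-stacking experiment.

    For each chronological prefix of the cube's dates, train/evaluate the
    classifier and record per-class PA plus OA and Kappa.  One stratified
    split is drawn on the full sample set and re-used across prefixes, so
    rows differ only by the bands available.
    """
    samples = extract_samples(cube, polygons)
    samples = stratified_split(samples, train_fraction, seed=seed)
    rows = []
    for sub in prefix_combinations(cube):
        sub_ids = [i for i, m in enumerate(cube.meta) if m in set(sub.meta)]
        sub_samples = LabeledSamples(
            pixel_ids=samples.pixel_ids,
            x=samples.x[:, sub_ids],
            y=samples.y,
            split=samples.split,
        )
        result = CropClassifier(
            sub, samples=sub_samples, n_trees=n_trees,
            train_fraction=train_fraction,
        ).fit(seed=seed)
        row: dict[str, object] = {
            "n_dates": len(sub.dates),
            "last_date": sub.dates[-1],
            "n_bands": sub.n_bands,
            "OA": result.oa,
            "Kappa": result.kappa,
        }
        for name in result.accuracy.pa.index:
            row[f"PA_{name}"] = result.accuracy.pa[name]
        rows.append(row)
    return pd.DataFrame(rows)
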