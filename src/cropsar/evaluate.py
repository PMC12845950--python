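"""Accuracy assessment and class separability.

Confusion-matrix metrics follow the standard remote-sensing definitions:
rows are predicted classes, columns ground truth;

    PA_j   = 100 * m[j, j] / colsum_j      (producer's accuracy, recall)
    UA_i   = 100 * m[i, i] / rowsum_i      (user's accuracy, precision)
    OA     = 100 * trace / total
    Kappa  = (p_o - p_e) / (1 - p_e),
             p_o = trace / total,  p_e = sum_i rowsum_i * colsum_i / total^2

Class separability is the Jeffries-Matusita distance
``JM = 2 (1 - exp(-DB))`` of the Gaussian Bhattacharyya distance

    DB = 1/8 (mu_p - mu_q)' M^-1 (mu_p - mu_q)
       + 1/2 ln( det M / sqrt(det S_p det S_q) ),   M = (S_p + S_q) / 2,

bounded in [0, 2]: 0 for identical class distributions, 2 for fully
separable ones (a JM above ~1.9 is conventionally read as well separable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .legend import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "SeparabilityResult",
    "confusion_matrix",
    "accuracy_report",
    "jm_distance",
    "jm_from_gaussian",
    "jm_matrix",
]


@dataclass
class ConfusionMatrix:
    """k x k count table; entry (i, j) = predicted class i, true class j."""

    counts: np.ndarray
    labels: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES.get(c, str(c)) for c in self.labels]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    predicted: np.ndarray,
    truth: np.ndarray,
    labels: list[int] | None = None,
) -> ConfusionMatrix:
    """Count table from paired label sequences.

    ``labels`` fixes the class set and order; by default the union of the
    observed codes, ascending.  Codes outside ``labels`` are an error.
    """
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if labels is None:
        labels = sorted(set(np.unique(predicted)) | set(np.unique(truth)))
    labels = [int(c) for c in labels]
    index = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    try:
        pi = np.array([index[int(c)] for c in predicted])
        ti = np.array([index[int(c)] for c in truth])
    except KeyError as exc:
        raise ValueError(f"unknown class code {exc.args[0]}") from None
    np.add.at(counts, (pi, ti), 1)
    return ConfusionMatrix(counts=counts, labels=labels)


@dataclass
class AccuracyReport:
    """Per-class PA/UA (percent), OA (percent) and Kappa.

    Classes with an empty truth column (PA) or prediction row (UA) are
    reported as NaN — undefined, not zero.
    """

    pa: pd.Series
    ua: pd.Series
    oa: float
    kappa: float
    matrix: ConfusionMatrix

    def summary(self) -> str:
        lines = [f"{'class':<12} {'PA %':>8} {'UA %':>8}"]
        for name in self.pa.index:
            pa = f"{self.pa[name]:.2f}" if np.isfinite(self.pa[name]) else "--"
            ua = f"{self.ua[name]:.2f}" if np.isfinite(self.ua[name]) else "--"
            lines.append(f"{name:<12} {pa:>8} {ua:>8}")
        lines.append(f"{'OA':<12} {self.oa:8.2f}")
        lines.append(f"{'Kappa':<12} {self.kappa:8.2f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"PA": self.pa, "UA": self.ua})


def accuracy_report(m: ConfusionMatrix) -> AccuracyReport:
    """PA/UA/OA/Kappa from a confusion matrix (formulas in module docstring)."""
    counts = m.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    diag = np.diag(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(colsum > 0, 100.0 * diag / np.where(colsum > 0, colsum, 1), np.nan)
        ua = np.where(rowsum > 0, 100.0 * diag / np.where(rowsum > 0, rowsum, 1), np.nan)
    p_o = diag.sum() / total
    p_e = float(rowsum @ colsum) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    names = [CLASS_NAMES.get(c, str(c)) for c in m.labels]
    return AccuracyReport(
        pa=pd.Series(pa, index=names),
        ua=pd.Series(ua, index=names),
        oa=100.0 * p_o,
        kappa=float(kappa),
        matrix=m,
    )


@dataclass(frozen=True)
class SeparabilityResult:
    """Bhattacharyya distance and its bounded JM transform for one pair."""

    db: float
    jm: float


def jm_from_gaussian(
    mu_p: np.ndarray,
    cov_p: np.ndarray,
    mu_q: np.ndarray,
    cov_q: np.ndarray,
) -> SeparabilityResult:
    """JM distance from Gaussian population parameters."""
    mu_p = np.atleast_1d(np.asarray(mu_p, dtype=float))
    mu_q = np.atleast_1d(np.asarray(mu_q, dtype=float))
    cov_p = np.atleast_2d(np.asarray(cov_p, dtype=float))
    cov_q = np.atleast_2d(np.asarray(cov_q, dtype=float))
    m = 0.5 * (cov_p + cov_q)
    diff = mu_p - mu_q
    sign_m, logdet_m = np.linalg.slogdet(m)
    sign_p, logdet_p = np.linalg.slogdet(cov_p)
    sign_q, logdet_q = np.linalg.slogdet(cov_q)
    if sign_m <= 0 or sign_p <= 0 or sign_q <= 0:
        raise np.linalg.LinAlgError("singular covariance in JM computation")
    db = 0.125 * float(diff @ np.linalg.solve(m, diff)) + 0.5 * (
        logdet_m - 0.5 * (logdet_p + logdet_q)
    )
    db = max(db, 0.0)
    return SeparabilityResult(db=db, jm=2.0 * (1.0 - np.exp(-db)))


def jm_distance(
    class_p_samples: np.ndarray,
    class_q_samples: np.ndarray,
    regularization: float = 1e-6,
) -> SeparabilityResult:
    """JM distance between two sample sets (multivariate-Gaussian model).

    Sample means and covariances are estimated per class; near-singular
    covariances are regularized by ``eps * mean-diagonal`` on the diagonal.
    """
    xp = np.atleast_2d(np.asarray(class_p_samples, dtype=float))
    xq = np.atleast_2d(np.asarray(class_q_samples, dtype=float))
    if xp.shape[1] != xq.shape[1]:
        raise ValueError("sample sets must share the feature dimension")
    if len(xp) < 2 or len(xq) < 2:
        raise ValueError("need at least 2 samples per class")

    def moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
        cov = np.atleast_2d(cov)
        eps = regularization * max(float(np.mean(np.diag(cov))), 1e-30)
        return mu, cov + eps * np.eye(cov.shape[0])

    mu_p, cov_p = moments(xp)
    mu_q, cov_q = moments(xq)
    try:
        return jm_from_gaussian(mu_p, cov_p, mu_q, cov_q)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular pooled covariance between the two sample sets "
            "(after regularization)"
        ) from None


def jm_matrix(
    samples_by_class: dict[int, np.ndarray],
    regularization: float = 1e-6,
) -> pd.DataFrame:
    """Symmetric JM matrix over all class pairs, as a labeled DataFrame."""
    codes = sorted(samples_by_class)
    names = [CLASS_NAMES.get(c, str(c)) for c in codes]
    out = pd.DataFrame(np.zeros((len(codes), len(codes))), index=names, columns=names)
    for i, ci in enumerate(codes):
        for j, cj in enumerate(codes):
            if j <= i:
                continue
            jm = jm_distance(
                samples_by_class[ci], samples_by_class[cj], regularization
            ).jm
            out.iloc[i, j] = jm
            out.iloc[j, i] = jm
    return out
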