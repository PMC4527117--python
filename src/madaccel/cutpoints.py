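"""MAD intensity cut-points via generalized ordinal logistic regression.

Three cumulative binary outcomes are modelled — class ≥ light, ≥ moderate
and ≥ vigorous — each by a logistic regression of the indicator on the
MAD value (mg) with a threshold-specific intercept α_k and slope β_k
("generalized" = non-proportional odds, so each threshold owns its
slope).  Repeated measures within a subject are handled by generalized
estimating equations with an exchangeable (compound-symmetry) working
correlation over subject clusters.

The cut-point for threshold k is the MAD where the fitted cumulative
probability crosses one half::

    cut_k = -α_k / β_k          (P(class ≥ k | MAD = cut_k) = 0.5)

When a threshold's classes are completely separated in MAD, the logistic
fit has no finite maximum; the estimator then falls back to the midpoint
of the empty gap between the classes and emits a prominent warning.

Classification uses lower-closed intervals: a MAD exactly equal to a
cut-point belongs to the higher class.  The universal adult cut-points
(17, 331, 599 mg) are provided as :data:`ADULT_UNIVERSAL_CUTS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ADULT_UNIVERSAL_CUTS",
    "ClassificationReport",
    "CutPointSet",
    "FitRejectedError",
    "OrdinalModelFit",
    "SeparationWarning",
    "ThresholdFit",
    "classify",
    "compare_cutpoint_sets",
    "evaluate",
    "fit_cutpoints",
]

N_CLASSES = 4


class FitRejectedError(RuntimeError):
    """The fitted model violates the requirements for usable cut-points."""


class SeparationWarning(UserWarning):
    """Complete separation forced a midpoint fallback estimate."""


@dataclass(frozen=True)
class CutPointSet:
    """Three strictly increasing MAD thresholds (mg) between classes."""

    cut1_mg: float
    cut2_mg: float
    cut3_mg: float

    def __post_init__(self) -> None:
        if not 0 < self.cut1_mg < self.cut2_mg < self.cut3_mg:
            raise ValueError(
                f"cut-points must satisfy 0 < cut1 < cut2 < cut3; got "
                f"({self.cut1_mg}, {self.cut2_mg}, {self.cut3_mg})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.cut1_mg, self.cut2_mg, self.cut3_mg])


#: Universal adult cut-points (mg) for sedentary→light, light→moderate,
#: moderate→vigorous, established from adult accelerometer calibration.
ADULT_UNIVERSAL_CUTS = CutPointSet(17.0, 331.0, 599.0)


@dataclass(frozen=True)
class ThresholdFit:
    """One cumulative threshold: logit P(class ≥ k) = alpha + beta·MAD."""

    threshold: int
    alpha: float
    beta: float
    method: str  # 'gee' or 'separation_midpoint'
    converged: bool
    working_correlation: float  # exchangeable parameter; NaN for fallback

    @property
    def cut_mg(self) -> float:
        return -self.alpha / self.beta


@dataclass(frozen=True)
class OrdinalModelFit:
    thresholds: tuple[ThresholdFit, ThresholdFit, ThresholdFit]

    @property
    def converged(self) -> bool:
        return all(t.converged for t in self.thresholds)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix and per-threshold binary metrics."""

    confusion: np.ndarray  # (4, 4) true class × predicted class
    misclassification_pct: float
    sensitivity: tuple[float, float, float]  # per cut k = 1..3
    specificity: tuple[float, float, float]
    accuracy: tuple[float, float, float]

    @property
    def n_values(self) -> int:
        return int(self.confusion.sum())


def _validate_fit_inputs(mad, classes, subjects):
    mad = np.asarray(mad, dtype=float)
    classes = np.asarray(classes, dtype=int)
    subjects = np.asarray(subjects)
    if not (mad.shape == classes.shape == subjects.shape) or mad.ndim != 1:
        raise ValueError("mad, classes and subjects must be equal-length 1-d")
    if set(np.unique(classes)) != set(range(N_CLASSES)):
        raise ValueError("all four intensity classes must be present")
    if np.unique(subjects).size < 2:
        raise ValueError("cut-point fitting requires at least 2 subjects")
    if (mad < 0).any() or not np.isfinite(mad).all():
        raise ValueError("MAD values must be finite and non-negative")
    return mad, classes, subjects


def _fit_one_threshold(
    k: int, mad: np.ndarray, y: np.ndarray, subjects: np.ndarray
) -> ThresholdFit:
    lo_max = mad[y == 0].max()
    hi_min = mad[y == 1].min()
    if hi_min > lo_max:
        # complete separation: the logistic likelihood has no finite
        # optimum, but any cut in the empty gap classifies perfectly
        cut = 0.5 * (lo_max + hi_min)
        warnings.warn(
            f"threshold {k}: classes completely separated in MAD "
            f"({lo_max:.1f} < {hi_min:.1f} mg); using gap midpoint "
            f"{cut:.1f} mg instead of a regression estimate",
            SeparationWarning,
            stacklevel=3,
        )
        # encode the midpoint as a steep logistic so cut = -alpha/beta
        beta = 1.0
        return ThresholdFit(k, -cut * beta, beta, "separation_midpoint",
                            True, float("nan"))
    exog = sm.add_constant(mad)
    model = sm.GEE(
        y,
        exog,
        groups=subjects,
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    alpha, beta = (float(v) for v in res.params)
    if not np.isfinite([alpha, beta]).all() or beta <= 0:
        raise FitRejectedError(
            f"threshold {k}: unusable fit (alpha={alpha:.3g}, beta={beta:.3g});"
            " a usable fit needs beta > 0"
        )
    dep = float(np.atleast_1d(res.cov_struct.dep_params).ravel()[0])
    return ThresholdFit(k, alpha, beta, "gee", bool(res.converged), dep)


def fit_cutpoints(
    mad_values: np.ndarray,
    true_classes: np.ndarray,
    subject_ids: np.ndarray,
) -> tuple[OrdinalModelFit, CutPointSet]:
    """Estimate the three MAD cut-points from labelled observations.

    Each observation is one MAD value with its pattern-based intensity
    class and its subject; subjects form the GEE correlation clusters.
    Raises :class:`FitRejectedError` if any slope is non-positive or the
    resulting cuts are not strictly increasing.
    """
    mad, classes, subjects = _validate_fit_inputs(
        mad_values, true_classes, subject_ids
    )
    fits = tuple(
        _fit_one_threshold(k, mad, (classes >= k).astype(float), subjects)
        for k in (1, 2, 3)
    )
    cuts = [f.cut_mg for f in fits]
    if not cuts[0] < cuts[1] < cuts[2]:
        raise FitRejectedError(
            f"non-monotone cut-points {np.round(cuts, 1)}; fit rejected"
        )
    return OrdinalModelFit(fits), CutPointSet(*cuts)


def classify(mad_mg, cuts: CutPointSet):
    """Ordinal intensity class of one or many MAD values.

    The class is the number of cut-points ≤ the MAD value, so intervals
    are lower-closed: MAD exactly at a cut belongs to the higher class.
    """
    mad = np.asarray(mad_mg, dtype=float)
    if (mad < 0).any():
        raise ValueError("MAD values must be non-negative")
    cls = (mad[..., None] >= cuts.as_array()).sum(axis=-1)
    return int(cls) if np.isscalar(mad_mg) else cls


def evaluate(
    mad_values: np.ndarray, true_classes: np.ndarray, cuts: CutPointSet
) -> ClassificationReport:
    """Confusion matrix, misclassification %, and per-cut binary metrics.

    Per-cut metrics collapse the ordinal scale at threshold k into
    {class < k} vs {class ≥ k}: sensitivity is the detection rate of
    truly ≥ k observations, specificity the rate for truly < k, accuracy
    the overall binary agreement.  A metric with an empty denominator is
    NaN.
    """
    mad = np.asarray(mad_values, dtype=float)
    truth = np.asarray(true_classes, dtype=int)
    if mad.shape != truth.shape or mad.ndim != 1:
        raise ValueError("mad_values and true_classes must be equal-length 1-d")
    if ((truth < 0) | (truth >= N_CLASSES)).any():
        raise ValueError("class labels must be in 0..3")
    pred = classify(mad, cuts)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(confusion, (truth, pred), 1)
    total = truth.size
    mis = 100.0 * (total - np.trace(confusion)) / total
    sens, spec, acc = [], [], []
    for k in (1, 2, 3):
        t = truth >= k
        p = pred >= k
        sens.append(float((p & t).sum() / t.sum()) if t.any() else float("nan"))
        spec.append(
            float((~p & ~t).sum() / (~t).sum()) if (~t).any() else float("nan")
        )
        acc.append(float((p == t).mean()))
    return ClassificationReport(
        confusion=confusion,
        misclassification_pct=float(mis),
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        accuracy=tuple(acc),
    )


def compare_cutpoint_sets(
    report_a: ClassificationReport,
    report_b: ClassificationReport,
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Side-by-side summary of two classification reports on the same data."""
    if report_a.n_values != report_b.n_values:
        raise ValueError("reports must be built on the same data")
    rows = []
    for name, rep in zip(names, (report_a, report_b)):
        row = {"cuts": name, "misclassification_pct": rep.misclassification_pct}
        for k in (1, 2, 3):
            row[f"sensitivity_cut{k}"] = rep.sensitivity[k - 1]
            row[f"specificity_cut{k}"] = rep.specificity[k - 1]
            row[f"accuracy_cut{k}"] = rep.accuracy[k - 1]
        rows.append(row)
    return pd.DataFrame(rows)
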