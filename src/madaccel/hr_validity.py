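"""Heart-rate validation of pattern-based intensity classes.

If the protocol's pattern-based intensity ordering is physiologically
valid, heart rate should rise approximately linearly with the movement
intensity a device measures.  This module computes, per subject, the
Pearson correlation between bout heart rate (mean of the 1-min and 2-min
readings) and bout MAD across the ambulatory activities, then pools the
subject-specific coefficients through the Fisher z-transform:

    pooled_r = tanh( mean_j arctanh(r_j) )

Sedentary bouts are excluded throughout: anticipatory excitement can
raise sedentary heart rate above light-activity heart rate, which says
nothing about the validity of the intensity ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationSummary",
    "UndefinedCorrelationError",
    "bout_mean_hr",
    "pooled_correlation",
    "subject_correlation",
]

MIN_BOUTS_PER_SUBJECT = 3


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or too few points)."""


@dataclass(frozen=True)
class CorrelationSummary:
    """Subject-level and Fisher-pooled HR-vs-MAD correlations."""

    per_subject_r: dict[str, float]
    pooled_r: float
    n_bouts_used: int
    excluded_subjects: tuple[str, ...] = field(default_factory=tuple)


def bout_mean_hr(hr_1min_bpm: float | None, hr_2min_bpm: float | None) -> float | None:
    """Mean of the 1-min and 2-min readings; the start reading is not used.

    Returns None (bout excluded) when either reading is missing.
    """
    if hr_1min_bpm is None or hr_2min_bpm is None:
        warnings.warn("bout excluded: missing heart-rate reading", stacklevel=2)
        return None
    return 0.5 * (float(hr_1min_bpm) + float(hr_2min_bpm))


def subject_correlation(
    mad_mg: np.ndarray,
    hr_bpm: np.ndarray,
    intensity_class: np.ndarray,
) -> float:
    """Pearson r between bout MAD and bout heart rate for one subject.

    Sedentary bouts (class 0) are dropped before correlating; at least
    three non-sedentary bouts with finite values are required.
    """
    mad = np.asarray(mad_mg, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    cls = np.asarray(intensity_class, dtype=int)
    if not (mad.shape == hr.shape == cls.shape):
        raise ValueError("inputs must have identical shapes")
    keep = (cls > 0) & np.isfinite(mad) & np.isfinite(hr)
    mad, hr = mad[keep], hr[keep]
    if mad.size < MIN_BOUTS_PER_SUBJECT:
        raise UndefinedCorrelationError(
            f"only {mad.size} usable non-sedentary bouts (need "
            f">= {MIN_BOUTS_PER_SUBJECT})"
        )
    if np.ptp(mad) == 0 or np.ptp(hr) == 0:
        raise UndefinedCorrelationError("zero variance in MAD or heart rate")
    return float(stats.pearsonr(mad, hr).statistic)


def pooled_correlation(per_subject_r) -> float:
    """Fisher z-transform pooling: tanh of the mean arctanh of the inputs.

    Accepts a sequence or a mapping of subject → r.  Coefficients at
    exactly ±1 are clamped just inside the open interval with a warning,
    since arctanh diverges there.
    """
    rs = np.asarray(
        list(per_subject_r.values()) if hasattr(per_subject_r, "values")
        else list(per_subject_r),
        dtype=float,
    )
    if rs.size == 0:
        raise ValueError("no correlation coefficients to pool")
    if (np.abs(rs) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    if (np.abs(rs) == 1).any():
        warnings.warn(
            "correlation of ±1 clamped before Fisher transform", stacklevel=2
        )
        rs = np.clip(rs, -(1 - 1e-12), 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(rs))))
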