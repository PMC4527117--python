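"""Bland-Altman agreement between paired device MAD values.

Agreement between two devices measuring the same sessions is summarised
the conventional way: for each paired observation the difference
(device A − device B) is plotted against the pair mean; the bias is the
mean difference and the 95 % limits of agreement are bias ± 1.96 × SD of
the differences (sample SD, n−1 denominator, no t-correction).

A threshold-stratified bias (default 700 mg) separates the low-
acceleration region, where devices with different dynamic ranges agree,
from the high-acceleration region where the narrow-range device clips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlandAltmanResult",
    "InsufficientPairsError",
    "PairedMads",
    "PairingError",
    "ThresholdBias",
    "bland_altman",
    "pair_bout_mads",
    "threshold_bias",
]


class PairingError(ValueError):
    """No paired observations could be formed."""


class InsufficientPairsError(ValueError):
    """Fewer pairs than the minimum the statistic requires."""


@dataclass(frozen=True)
class PairedMads:
    """Inner-joined MAD pairs plus the keys that failed to match."""

    pairs: pd.DataFrame  # key columns + mad_a, mad_b
    unmatched: pd.DataFrame  # key columns + side ('a' or 'b')

    @property
    def mad_a(self) -> np.ndarray:
        return self.pairs["mad_a"].to_numpy()

    @property
    def mad_b(self) -> np.ndarray:
        return self.pairs["mad_b"].to_numpy()


@dataclass(frozen=True)
class BlandAltmanResult:
    pair_means: np.ndarray
    pair_diffs: np.ndarray
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float


@dataclass(frozen=True)
class ThresholdBias:
    """Mean difference below/above a pair-mean threshold; NaN if empty."""

    threshold_mg: float
    bias_below: float
    bias_above: float
    n_below: int
    n_above: int


def pair_bout_mads(
    mads_a: pd.DataFrame,
    mads_b: pd.DataFrame,
    keys: tuple[str, ...] = ("participant", "bout_index", "epoch_slot"),
    level: str = "epoch",
) -> PairedMads:
    """Join two per-device MAD tables on identical observation keys.

    Both tables need the key columns and a ``mad_mg`` column.  With
    ``level="bout"`` the three epoch MADs of each bout are averaged before
    pairing (the epoch_slot key is dropped).  Unmatched keys are reported
    in the result, never silently discarded.
    """
    if level not in {"epoch", "bout"}:
        raise ValueError("level must be 'epoch' or 'bout'")
    keys = list(keys)
    if level == "bout" and "epoch_slot" in keys:
        keys = [k for k in keys if k != "epoch_slot"]
        mads_a = mads_a.groupby(keys, as_index=False)["mad_mg"].mean()
        mads_b = mads_b.groupby(keys, as_index=False)["mad_mg"].mean()
    a = mads_a[keys + ["mad_mg"]].rename(columns={"mad_mg": "mad_a"})
    b = mads_b[keys + ["mad_mg"]].rename(columns={"mad_mg": "mad_b"})
    merged = a.merge(b, on=keys, how="outer", indicator=True)
    matched = merged[merged["_merge"] == "both"].drop(columns="_merge")
    unmatched = merged[merged["_merge"] != "both"].copy()
    unmatched["side"] = unmatched["_merge"].map(
        {"left_only": "a", "right_only": "b"}
    )
    unmatched = unmatched[keys + ["side"]]
    if len(matched) == 0:
        raise PairingError("no (participant, bout, epoch) keys matched")
    return PairedMads(
        pairs=matched.reset_index(drop=True),
        unmatched=unmatched.reset_index(drop=True),
    )


def bland_altman(mad_a: np.ndarray, mad_b: np.ndarray) -> BlandAltmanResult:
    """Bias and 95 % limits of agreement for paired measurements (A − B)."""
    a = np.asarray(mad_a, dtype=float)
    b = np.asarray(mad_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d arrays")
    if a.size < 3:
        raise InsufficientPairsError("Bland-Altman needs at least 3 pairs")
    diffs = a - b
    means = 0.5 * (a + b)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        pair_means=means,
        pair_diffs=diffs,
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def threshold_bias(
    mad_a: np.ndarray, mad_b: np.ndarray, threshold_mg: float = 700.0
) -> ThresholdBias:
    """Mean difference (A − B) stratified by pair mean ≤/> a threshold.

    An empty stratum yields NaN for its bias rather than an error.
    """
    a = np.asarray(mad_a, dtype=float)
    b = np.asarray(mad_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be equal-length non-empty 1-d arrays")
    diffs = a - b
    means = 0.5 * (a + b)
    below = diffs[means <= threshold_mg]
    above = diffs[means > threshold_mg]
    return ThresholdBias(
        threshold_mg=threshold_mg,
        bias_below=float(below.mean()) if below.size else float("nan"),
        bias_above=float(above.mean()) if above.size else float("nan"),
        n_below=int(below.size),
        n_above=int(above.size),
    )
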