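"""Leaf physiology and replicate-quality utilities.

Relative water content: RWC (%) = ((FW - DW) / (TW - DW)) * 100, with fresh
weight FW, turgid weight TW (after 24 h submersion) and oven-dry weight DW.
Replicate quality: least-squares simple linear regression of replicate 2 on
replicate 1 (raw FPKM by default, log scale configurable), reporting R^2 and
slope for QC gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class LeafWeights:
    """Fresh, turgid, and dry weights of one leaf sample (grams)."""

    fw: float
    tw: float
    dw: float

    def __post_init__(self):
        if self.tw <= self.dw:
            raise ValidationError(
                "turgid weight must exceed dry weight (zero or negative "
                "water-holding capacity)")


def compute_rwc(weights: LeafWeights) -> float:
    """Relative water content in percent: ((FW - DW) / (TW - DW)) * 100."""
    return (weights.fw - weights.dw) / (weights.tw - weights.dw) * 100.0


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


def replicate_regression(rep1, rep2, log: bool = False,
                         epsilon: float = 1e-3) -> RegressionResult:
    """Regress replicate 2 on replicate 1 across genes.

    With ``log=True`` both vectors are log2(x + epsilon)-transformed first.
    Requires n >= 3 paired observations and non-degenerate rep1 variance.
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("replicate vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if log:
        x = np.log2(x + epsilon)
        y = np.log2(y + epsilon)
    if np.allclose(x, x[0]):
        raise ValidationError("replicate 1 has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(r_squared=float(fit.rvalue ** 2),
                            slope=float(fit.slope),
                            intercept=float(fit.intercept), n=int(x.size))
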