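"""Tri-state response calls from per-contrast differential statistics.

A gene is called significantly differentially expressed in a contrast when
all three criteria hold:

1. FDR-adjusted p-value (Benjamini-Hochberg q) at most ``q_max`` (default
   0.05, inclusive);
2. absolute log2 fold change at least ``min_abs_log2fc`` (default 1.0,
   inclusive; an infinite fold change from a zero denominator qualifies);
3. the FPKM of at least one of the two contrasted samples strictly exceeds
   the ``floor_percentile``-th percentile (default 25) of that sample's
   genome-wide FPKM distribution.

Significant genes are called ``up`` or ``down`` by the sign of the fold
change; everything else (including rows whose test status is not ``OK``) is
``nochange``.

The module also provides a declared stand-in differential-expression test
(:func:`simple_de_test`) so synthetic FPKM matrices can be processed
end-to-end without an external cuffdiff run.  The default is a moderated
two-sample t statistic on log2(FPKM + eps): with only two biological
replicates per condition an unmoderated per-gene variance has ~2 degrees of
freedom and essentially no power after FDR correction, so the per-gene
variance is shrunk toward the genome-wide mean variance with a configurable
prior weight (empirical-Bayes style).  An unmoderated Welch test is available
via ``method="welch"``.  Outputs carry ``de_method`` metadata so downstream
consumers can tell the stand-in from an external cuffdiff table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CONTRAST_CONDITIONS, DIFF_COLUMNS, sample_columns

CALLS = ("up", "down", "nochange")


@dataclass(frozen=True)
class SignificanceCriteria:
    """The three-part significance rule; defaults reproduce the study rule."""

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    floor_percentile: float = 25.0
    #: reference distribution for the floor; currently the full per-sample
    #: FPKM vector over all genes
    percentile_reference: str = "per_sample_all_genes"

    def __post_init__(self):
        if not (0 < self.q_max <= 1):
            raise ValidationError("q_max must lie in (0, 1]")
        if not (0 <= self.floor_percentile <= 100):
            raise ValidationError("floor_percentile must lie in [0, 100]")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expression_floor(fpkm_sample, percentile: float) -> float:
    """Percentile of one sample's genome-wide FPKM distribution.

    Linear interpolation between closest ranks (the numpy default), so the
    definition is explicit and reproducible.
    """
    values = np.asarray(fpkm_sample, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take a percentile of an empty sample")
    if (values < 0).any():
        raise ValidationError("FPKM values must be non-negative")
    return float(np.percentile(values, percentile))


def _criteria_frame(diff: pd.DataFrame, floors: dict[str, float],
                    crit: SignificanceCriteria) -> pd.DataFrame:
    contrast = diff["contrast"].iloc[0]
    cond_a, cond_b = CONTRAST_CONDITIONS[contrast]
    ok = diff["status"].eq("OK")
    pass_q = ok & diff["q_value"].le(crit.q_max)
    pass_fc = ok & diff["log2_fc"].abs().ge(crit.min_abs_log2fc)
    pass_floor = ok & (diff["value_a"].gt(floors[cond_a])
                       | diff["value_b"].gt(floors[cond_b]))
    return pd.DataFrame({"pass_q": pass_q.fillna(False),
                         "pass_fc": pass_fc.fillna(False),
                         "pass_floor": pass_floor.fillna(False)})


def call_responses(diff: pd.DataFrame,
                   crit: SignificanceCriteria = SignificanceCriteria(),
                   floors: dict[str, float] | None = None) -> pd.DataFrame:
    """Tri-state calls for every record of one contrast's diff table.

    ``floors`` maps condition names to FPKM thresholds; when omitted they are
    computed from the table's own value_a / value_b distributions at
    ``crit.floor_percentile``.  Returns the diff frame plus ``call`` and the
    three ``pass_*`` criterion columns.
    """
    if diff.empty:
        out = diff.copy()
        out[["call", "pass_q", "pass_fc", "pass_floor"]] = None
        return out
    contrasts = diff["contrast"].unique()
    if len(contrasts) != 1:
        raise ValidationError(f"expected a single contrast, got {list(contrasts)}")
    cond_a, cond_b = CONTRAST_CONDITIONS[contrasts[0]]
    if floors is None:
        floors = {
            cond_a: expression_floor(diff["value_a"], crit.floor_percentile),
            cond_b: expression_floor(diff["value_b"], crit.floor_percentile),
        }
    crits = _criteria_frame(diff, floors, crit)
    significant = crits.all(axis=1) & diff["log2_fc"].ne(0)
    call = np.where(significant & diff["log2_fc"].gt(0), "up",
                    np.where(significant & diff["log2_fc"].lt(0), "down",
                             "nochange"))
    out = diff.copy()
    out["call"] = call
    out[crits.columns] = crits
    return out


def call_response(rec, floors: dict[str, float],
                  crit: SignificanceCriteria = SignificanceCriteria()) -> str:
    """Scalar convenience wrapper: one DiffRecord row -> 'up'/'down'/'nochange'."""
    frame = pd.DataFrame([rec]) if not isinstance(rec, pd.DataFrame) else rec
    return call_responses(frame, crit, floors)["call"].iloc[0]


# -- stand-in differential-expression test -----------------------------------

def _condition_stats(fpkm: pd.DataFrame, condition: str, epsilon: float):
    cols = sample_columns(fpkm, condition)
    if len(cols) < 2:
        raise ValidationError(
            f"condition {condition!r} has {len(cols)} replicate(s); the "
            "stand-in DE test needs at least 2 - supply external diff tables "
            "instead")
    x = np.log2(fpkm[cols].to_numpy(dtype=float) + epsilon)
    return (fpkm[cols].mean(axis=1).to_numpy(),
            x.mean(axis=1), x.var(axis=1, ddof=1), len(cols))


def simple_de_test(fpkm: pd.DataFrame, contrast: str, *,
                   epsilon: float = 1e-3, method: str = "moderated",
                   prior_df: float = 20.0) -> pd.DataFrame:
    """Per-gene differential test between the two conditions of a contrast.

    value_a / value_b are replicate means on the FPKM scale; the fold change
    is ``log2((mean_b + eps) / (mean_a + eps))``; p comes from a two-sided
    two-sample t on log2(FPKM + eps), with the per-gene variance shrunk
    toward the genome-wide mean variance (``method="moderated"``, prior
    weight ``prior_df``) or left unmoderated (``method="welch"``); q is the
    Benjamini-Hochberg adjustment over all genes in the table.
    """
    if method not in ("moderated", "welch"):
        raise ValidationError(f"unknown DE method {method!r}")
    cond_a, cond_b = CONTRAST_CONDITIONS[contrast]
    mean_a, la, va, na = _condition_stats(fpkm, cond_a, epsilon)
    mean_b, lb, vb, nb = _condition_stats(fpkm, cond_b, epsilon)
    delta = lb - la

    if method == "welch":
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(se2)
            df_w = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                               + (vb / nb) ** 2 / (nb - 1))
        p = 2 * stats.t.sf(np.abs(t), df_w)
    else:
        dg = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / dg
        s0 = float(np.mean(pooled))
        shrunk = (prior_df * s0 + dg * pooled) / (prior_df + dg)
        se2 = shrunk * (1 / na + 1 / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), prior_df + dg)
    # zero-variance degenerate genes: identical replicates in both conditions
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(delta != 0, 0.0, 1.0), p)

    out = pd.DataFrame({
        "gene_id": fpkm.index.astype(str),
        "contrast": contrast,
        "value_a": mean_a,
        "value_b": mean_b,
        "log2_fc": np.log2((mean_b + epsilon) / (mean_a + epsilon)),
        "p_value": p,
        "q_value": benjamini_hochberg(p),
        "status": "OK",
    })[DIFF_COLUMNS]
    out.attrs["de_method"] = f"stand-in:{method}"
    return out
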