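"""Nine-way memory / non-memory / late-response partition of the gene universe.

Each gene carries two tri-state calls: S1 vs W (first symbol) and S3 vs S1
(second symbol).  The pair maps onto nine classes:

* memory: ``[+/+] [-/-] [+/-] [-/+]`` - responded in S1 and responded again,
  differently, in S3;
* non-memory: ``[+/=] [-/=]`` - responded in S1, S3 statistically
  indistinguishable from S1;
* late response: ``[=/+] [=/-]`` - unchanged in S1 but changed in S3 (computed
  and reported, excluded from memory statistics);
* non-responsive: ``[=/=]``.

Note that ``=`` means "failed the significance criteria", not a demonstrated
equivalence.  Class symbols serialize exactly as the bracket notation above.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import sample_columns

PP, MM, PM, MP = "[+/+]", "[-/-]", "[+/-]", "[-/+]"
PE, ME, EP, EM, EE = "[+/=]", "[-/=]", "[=/+]", "[=/-]", "[=/=]"

MEMORY_CLASSES = (PP, MM, PM, MP)
NON_MEMORY_CLASSES = (PE, ME)
LATE_CLASSES = (EP, EM)
RESPONSE_CLASSES = MEMORY_CLASSES + NON_MEMORY_CLASSES  # S1 responders
SIX_CLASSES = (PP, MM, PM, MP, PE, ME)  # the reported class columns
ALL_CLASSES = MEMORY_CLASSES + NON_MEMORY_CLASSES + LATE_CLASSES + (EE,)

_SIGN = {"up": "+", "down": "-", "nochange": "="}
_CLASS_BY_PAIR = {(a, b): f"[{_SIGN[a]}/{_SIGN[b]}]"
                  for a in _SIGN for b in _SIGN}


def classify_gene(call_s1: str, call_s3: str) -> str:
    """Map one gene's (S1 vs W, S3 vs S1) call pair to its class symbol."""
    try:
        return _CLASS_BY_PAIR[(call_s1, call_s3)]
    except KeyError:
        raise ValidationError(
            f"calls must be up/down/nochange, got ({call_s1!r}, {call_s3!r})")


def classify_genes(calls_s1: pd.DataFrame, calls_s3: pd.DataFrame) -> pd.DataFrame:
    """Join the two per-contrast call tables and classify every gene.

    Both tables must cover the same gene universe; asymmetric gene sets raise
    with the offending ids.  Returns gene_id, call_s1, call_s3, class,
    memory_flag.
    """
    s1 = calls_s1.set_index("gene_id")["call"]
    s3 = calls_s3.set_index("gene_id")["call"]
    only_s1 = s1.index.difference(s3.index)
    only_s3 = s3.index.difference(s1.index)
    if len(only_s1) or len(only_s3):
        raise ValidationError(
            "gene sets differ between contrasts; e.g. "
            f"only in S1 table: {list(only_s1[:3])}, "
            f"only in S3 table: {list(only_s3[:3])}")
    out = pd.DataFrame({"call_s1": s1, "call_s3": s3.reindex(s1.index)})
    out["class"] = [_CLASS_BY_PAIR[pair]
                    for pair in zip(out["call_s1"], out["call_s3"])]
    out["memory_flag"] = out["class"].isin(MEMORY_CLASSES)
    return out.rename_axis("gene_id").reset_index()


@dataclass(frozen=True)
class ClassSummary:
    """Per-class gene counts and the derived partition totals."""

    counts: dict

    @classmethod
    def from_counts(cls, counts: dict) -> "ClassSummary":
        full = {c: int(counts.get(c, 0)) for c in ALL_CLASSES}
        extra = set(counts) - set(ALL_CLASSES)
        if extra:
            raise ValidationError(f"unknown class symbols {sorted(extra)}")
        return cls(full)

    @classmethod
    def from_labels(cls, labels) -> "ClassSummary":
        return cls.from_counts(Counter(labels))

    def __getitem__(self, symbol: str) -> int:
        return self.counts[symbol]

    @property
    def total_genes(self) -> int:
        return sum(self.counts.values())

    @property
    def induced(self) -> int:
        return self[PP] + self[PM] + self[PE]

    @property
    def repressed(self) -> int:
        return self[MM] + self[MP] + self[ME]

    @property
    def dehydration_response(self) -> int:
        return self.induced + self.repressed

    @property
    def memory_total(self) -> int:
        return sum(self[c] for c in MEMORY_CLASSES)

    @property
    def non_memory_total(self) -> int:
        return sum(self[c] for c in NON_MEMORY_CLASSES)

    @property
    def late_total(self) -> int:
        return sum(self[c] for c in LATE_CLASSES)

    @property
    def memory_fraction(self) -> float | None:
        """memory_total / dehydration_response, None when there are no
        responders (flagged rather than NaN)."""
        if self.dehydration_response == 0:
            return None
        return self.memory_total / self.dehydration_response

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "dehydration_response": self.dehydration_response,
            "induced": self.induced,
            "repressed": self.repressed,
            "memory_total": self.memory_total,
            "non_memory_total": self.non_memory_total,
            "late_total": self.late_total,
            "memory_fraction": self.memory_fraction,
            "classes": dict(self.counts),
        }


def summarize_classes(labels) -> ClassSummary:
    """Count the class labels of the gene universe into a ClassSummary."""
    return ClassSummary.from_labels(labels)


def write_summary_json(summary: ClassSummary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2)


def scatter_coordinates(fpkm: pd.DataFrame, labels: pd.DataFrame,
                        epsilon: float = 1e-3) -> pd.DataFrame:
    """Per-gene plotting coordinates for the response-distribution scatter.

    x is log2 of the S1-level mean FPKM; y1 the log2 S1/W ratio; y2 the log2
    S3/W ratio (with the epsilon pseudocount guarding zeros); the class label
    is carried as the color key.  Revised-response classes sit near y2 = 0.
    """
    means = {c: fpkm[sample_columns(fpkm, c)].mean(axis=1) for c in ("W", "S1", "S3")}
    coords = pd.DataFrame({
        "x": np.log2(means["S1"] + epsilon),
        "y1": np.log2((means["S1"] + epsilon) / (means["W"] + epsilon)),
        "y2": np.log2((means["S3"] + epsilon) / (means["W"] + epsilon)),
    }, index=fpkm.index)
    cls = labels.set_index("gene_id")["class"]
    coords["class"] = cls.reindex(coords.index)
    return coords.rename_axis("gene_id").reset_index()
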