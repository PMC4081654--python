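"""Cross-species comparison of memory responses through homolog maps.

Each maize memory gene maps to zero or more reference-species (Arabidopsis)
genes; the reference genes carry their own nine-way class labels, consumed
as input rather than recomputed.  Per maize gene a conservation verdict is
derived with ANY-homolog semantics and a fixed precedence (a single homolog
sharing the exact class symbol suffices):

``memory_same_type > memory_different_type > homolog_non_memory >
homolog_no_response``; genes without homologs are ``no_homolog``.

The homolog-level partition counts reference genes by their own response:
no S1 response (first symbol '='), responds without memory, responds with
memory.  Because maps are many-to-many, gene-level (maize) and
homolog-level tallies differ; both are reported.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError
from .memory import ALL_CLASSES, MEMORY_CLASSES, NON_MEMORY_CLASSES

VERDICTS = ("memory_same_type", "memory_different_type",
            "homolog_non_memory", "homolog_no_response", "no_homolog")

_NO_S1_RESPONSE = ("[=/=]", "[=/+]", "[=/-]")


def _check_classes(values, what: str) -> None:
    bad = set(values) - set(ALL_CLASSES)
    if bad:
        raise ValidationError(f"unknown class symbols in {what}: {sorted(bad)}")


def homolog_outcome(ref_class: str) -> str:
    """One reference gene's own response category."""
    if ref_class in MEMORY_CLASSES:
        return "responds_memory"
    if ref_class in NON_MEMORY_CLASSES:
        return "responds_non_memory"
    return "no_S1_response"


def partition_homologs(homolog_map: pd.DataFrame,
                       ref_classes: pd.Series) -> dict[str, int]:
    """Partition the mapped reference genes by their own response.

    Counts are over *unique* reference gene ids and sum to the size of the
    mapped homolog universe.  A mapped homolog without a class label raises,
    listing the offending ids.
    """
    _check_classes(ref_classes, "ref_classes")
    homologs = pd.unique(homolog_map["ref_id"])
    missing = [h for h in homologs if h not in ref_classes.index]
    if missing:
        raise ValidationError(f"homologs without class labels: {missing[:5]}")
    counts = {"no_S1_response": 0, "responds_non_memory": 0,
              "responds_memory": 0}
    for h in homologs:
        counts[homolog_outcome(ref_classes[h])] += 1
    counts["total_homologs"] = len(homologs)
    return counts


def conservation_verdict(maize_class: str, homolog_classes) -> str:
    """Verdict for one maize memory gene given its homologs' classes."""
    homolog_classes = list(homolog_classes)
    if not homolog_classes:
        return "no_homolog"
    if any(h == maize_class for h in homolog_classes):
        return "memory_same_type"
    if any(h in MEMORY_CLASSES for h in homolog_classes):
        return "memory_different_type"
    if any(h in NON_MEMORY_CLASSES for h in homolog_classes):
        return "homolog_non_memory"
    return "homolog_no_response"


def conservation_verdicts(maize_classes: pd.Series,
                          homolog_map: pd.DataFrame,
                          ref_classes: pd.Series) -> pd.DataFrame:
    """Per-maize-gene conservation records.

    ``maize_classes``: class label per maize memory gene (index gene id);
    ``homolog_map``: columns (maize_id, ref_id); ``ref_classes``: class per
    reference gene.  Verdicts are order-invariant over homolog enumeration.
    """
    _check_classes(maize_classes, "maize_classes")
    _check_classes(ref_classes, "ref_classes")
    mapped = homolog_map[homolog_map["maize_id"].isin(maize_classes.index)]
    missing = mapped.loc[~mapped["ref_id"].isin(ref_classes.index), "ref_id"]
    if len(missing):
        raise ValidationError(
            f"homologs without class labels: {sorted(set(missing))[:5]}")
    by_gene = mapped.groupby("maize_id")["ref_id"].agg(list)
    rows = []
    for gene in maize_classes.index:
        refs = by_gene.get(gene, [])
        outcomes = [ref_classes[r] for r in refs]
        rows.append({
            "maize_gene_id": gene,
            "maize_class": maize_classes[gene],
            "n_homologs": len(refs),
            "homolog_classes": ";".join(outcomes),
            "verdict": conservation_verdict(maize_classes[gene], outcomes),
        })
    return pd.DataFrame(rows)


def figure_tables(records: pd.DataFrame, homolog_map: pd.DataFrame,
                  ref_classes: pd.Series) -> dict:
    """Nested count tables describing the conservation partition.

    Returns the overall homolog-level partition (unique reference genes and
    the multiset of (maize, homolog) pairs - the two differ for many-to-many
    maps), the maize-gene-level verdict counts, and a per-maize-class
    breakdown of both verdicts and homolog outcomes.
    """
    if records.empty:
        return {"homolog_partition": {}, "pair_partition": {},
                "verdict_counts": {}, "per_maize_class": {}}
    mapped = homolog_map[homolog_map["maize_id"].isin(records["maize_gene_id"])]
    partition = partition_homologs(mapped, ref_classes) if len(mapped) else {
        "no_S1_response": 0, "responds_non_memory": 0, "responds_memory": 0,
        "total_homologs": 0}
    pair_outcomes = mapped["ref_id"].map(
        lambda r: homolog_outcome(ref_classes[r]))
    pair_partition = pair_outcomes.value_counts().to_dict()
    pair_partition["total_pairs"] = int(len(mapped))

    verdict_counts = records["verdict"].value_counts().to_dict()
    per_class = {}
    for cls, sub in records.groupby("maize_class"):
        cls_map = mapped[mapped["maize_id"].isin(sub["maize_gene_id"])]
        outcome_tally = cls_map["ref_id"].map(
            lambda r: homolog_outcome(ref_classes[r])).value_counts().to_dict()
        same_type = cls_map["ref_id"].map(
            lambda r: ref_classes[r] == cls).sum()
        per_class[cls] = {
            "n_maize_genes": int(len(sub)),
            "verdicts": sub["verdict"].value_counts().to_dict(),
            "homolog_outcomes": outcome_tally,
            "homologs_same_class": int(same_type),
        }
    return {"homolog_partition": partition,
            "pair_partition": pair_partition,
            "verdict_counts": verdict_counts,
            "per_maize_class": per_class}
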