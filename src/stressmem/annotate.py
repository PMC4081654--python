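"""Homology-based annotation transfer.

For every query protein the BLAST hit list (already filtered at e <= 1e-3 by
the search itself) is sorted by ascending e-value, descending alignment
length and descending percent identity; the best-e-value *window* keeps every
hit whose e-value is within a 1e10 multiplicative factor of the best hit
(inclusive: a best hit at 1e-63 admits hits up to 1e-53).  From the window
members' reference descriptions a functional description is synthesized as
the top 3 longest substrings common to all of them, and for each GO domain
the 10 most frequent terms among the window's reference genes are collected.

The native description is kept when present; "hypothetical protein" /
"putative protein" placeholders count as absent.  GO terms are always taken
from the window, never from the native annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GO_DOMAINS

#: multiplicative width of the e-value window
WINDOW_FACTOR = 1e10
#: absolute guard used when the best e-value is exactly 0 (the multiplicative
#: rule degenerates); hits at or below this e-value stay in the window
ZERO_BEST_GUARD = 1e-170
#: relative tolerance so that decade arithmetic at the window boundary
#: (1e-63 * 1e10 vs 1e-53) is not broken by floating-point rounding
_REL_TOL = 1e-9

_PLACEHOLDER_RE = re.compile(
    r"^(hypothetical|putative)(\s+protein)?\.?$", re.IGNORECASE)


def sort_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (e-value asc, length desc, pid desc, subject id asc)."""
    return hits.sort_values(
        ["evalue", "length", "pident", "sseqid"],
        ascending=[True, False, False, True],
        kind="mergesort").reset_index(drop=True)


@dataclass
class HitWindow:
    """Best-e-value window of one query's sorted hits."""

    query_id: str
    hits: pd.DataFrame
    e_cutoff: float

    @property
    def subject_ids(self) -> list[str]:
        return list(self.hits["sseqid"])

    def __len__(self) -> int:
        return len(self.hits)


def evalue_window(sorted_hits: pd.DataFrame, *,
                  factor: float = WINDOW_FACTOR,
                  zero_guard: float = ZERO_BEST_GUARD) -> HitWindow:
    """Retain every hit with e-value <= best_e * factor (inclusive).

    When the best e-value is exactly 0 the multiplicative rule degenerates;
    the window then keeps hits with e = 0 plus hits at or below
    ``zero_guard``, preserving the closest-homology intent.
    An empty input yields an empty window.
    """
    if sorted_hits.empty:
        return HitWindow("", sorted_hits.copy(), 0.0)
    query_id = str(sorted_hits["qseqid"].iloc[0])
    best = float(sorted_hits["evalue"].iloc[0])
    if float(sorted_hits["evalue"].min()) < best:
        raise ValidationError("hits are not sorted; apply sort_hits first")
    if best == 0.0:
        cutoff = zero_guard
    else:
        cutoff = best * factor
    keep = sorted_hits["evalue"] <= cutoff * (1 + _REL_TOL)
    return HitWindow(query_id, sorted_hits[keep].reset_index(drop=True), cutoff)


# -- longest common substrings ------------------------------------------------

def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", str(text)).strip().lower()


def _trim_to_words(sub: str, host: str, start: int) -> str:
    """Drop partial edge tokens when the match boundary cuts a word in the
    host string, then strip surrounding whitespace."""
    end = start + len(sub)
    if start > 0 and host[start - 1].isalnum() and sub and sub[0].isalnum():
        cut = re.search(r"[^\w]", sub)
        sub = sub[cut.start():] if cut else ""
    if end < len(host) and host[end].isalnum() and sub and sub[-1].isalnum():
        cut = re.search(r"[^\w](?=\w*$)", sub)
        sub = sub[:cut.start() + 1] if cut else ""
    return sub.strip()


def common_substrings(descriptions, k: int = 3, min_len: int = 4,
                      trim_words: bool = True) -> list[str]:
    """Top-k longest substrings common to *all* descriptions.

    Descriptions are case-folded and whitespace-collapsed first.  Selection
    is greedy: the longest substring of the shortest description present in
    every description wins (ties broken by first occurrence), its occurrences
    are masked in every description so later picks cannot overlap it, and the
    search repeats up to ``k`` times.  Candidates shorter than ``min_len``
    are discarded; with ``trim_words`` the results are trimmed to word
    boundaries of the host description.
    """
    texts = [_normalize(d) for d in descriptions]
    if not texts or any(t == "" for t in texts):
        return []
    host_original = min(texts, key=len)
    masked = list(texts)
    results: list[str] = []
    for _ in range(k):
        host = min(masked, key=len)
        found = None
        for length in range(len(host), min_len - 1, -1):
            for start in range(len(host) - length + 1):
                sub = host[start:start + length]
                if "\x00" in sub:
                    continue
                if all(sub in m for m in masked):
                    found = (sub, start)
                    break
            if found:
                break
        if not found:
            break
        sub, start = found
        masked = [m.replace(sub, "\x00" * len(sub)) for m in masked]
        if trim_words:
            pos = host_original.find(sub)
            rendered = (_trim_to_words(sub, host_original, pos)
                        if pos >= 0 else sub.strip())
        else:
            rendered = sub
        if len(rendered) >= min_len:
            results.append(rendered)
    return results


# -- GO aggregation -----------------------------------------------------------

_ISOFORM_RE = re.compile(r"\.\d+$")


def protein_to_gene(protein_id: str) -> str:
    """Strip a trailing isoform suffix (AT1G01010.1 -> AT1G01010)."""
    return _ISOFORM_RE.sub("", str(protein_id))


def aggregate_go(window: HitWindow, annotations: pd.DataFrame,
                 top_n: int = 10) -> dict[str, list[tuple[str, int]]]:
    """Per-domain top-``top_n`` GO terms among the window's reference genes.

    Protein isoform ids map to gene ids before lookup; each term is counted
    once per unique (reference gene, term) pair, ranked by descending count
    with a lexical tiebreak.
    """
    genes = {protein_to_gene(s) for s in window.subject_ids}
    member = annotations[annotations["gene_id"].isin(genes)]
    out: dict[str, list[tuple[str, int]]] = {}
    for domain in GO_DOMAINS:
        sub = member[member["domain"] == domain]
        pairs = sub.drop_duplicates(subset=["gene_id", "term"])
        counts = pairs.groupby("term").size()
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[domain] = ranked[:top_n]
    return out


@dataclass
class InferredAnnotation:
    """Transferred annotation of one query protein."""

    query_id: str
    description: str
    source: str  # 'native' or 'inferred'
    go_terms: dict = field(default_factory=dict)
    unannotated: bool = False


def native_is_absent(description: str | None) -> bool:
    if description is None:
        return True
    text = _normalize(description)
    return text == "" or bool(_PLACEHOLDER_RE.match(text))


def infer_annotation(query_id: str, native_description: str | None,
                     window: HitWindow, annotations: pd.DataFrame,
                     subject_descriptions: pd.Series,
                     k: int = 3, min_len: int = 4) -> InferredAnnotation:
    """Assemble one query's annotation from its hit window.

    The description stays native when a real one exists; otherwise it is the
    '; '-joined longest-common-substring synthesis of the window members'
    reference descriptions.  GO terms always come from :func:`aggregate_go`.
    A query with no hits is returned empty and flagged unannotated.
    """
    if len(window) == 0:
        return InferredAnnotation(query_id, native_description or "",
                                  source="native" if not native_is_absent(
                                      native_description) else "inferred",
                                  go_terms={d: [] for d in GO_DOMAINS},
                                  unannotated=True)
    go_terms = aggregate_go(window, annotations)
    if not native_is_absent(native_description):
        return InferredAnnotation(query_id, str(native_description),
                                  source="native", go_terms=go_terms)
    genes = {protein_to_gene(s) for s in window.subject_ids}
    descs = [subject_descriptions[g] for g in sorted(genes)
             if g in subject_descriptions.index
             and str(subject_descriptions[g]).strip()]
    description = "; ".join(common_substrings(descs, k=k, min_len=min_len))
    return InferredAnnotation(query_id, description, source="inferred",
                              go_terms=go_terms,
                              unannotated=not description and not any(
                                  go_terms.values()))


def _render_terms(terms: list[tuple[str, int]]) -> str:
    return ";".join(f"{t}({n})" for t, n in terms)


def annotate_all(blast: pd.DataFrame, native_descriptions: pd.Series,
                 subject_descriptions: pd.Series, annotations: pd.DataFrame,
                 queries=None) -> pd.DataFrame:
    """Run the full transfer for every query in the BLAST table.

    ``queries`` widens the output to ids without hits (flagged unannotated).
    Output columns: query_id, source, description, cc_terms, mf_terms,
    bp_terms ('term(count)' ';'-joined).
    """
    grouped = dict(tuple(blast.groupby("qseqid"))) if not blast.empty else {}
    all_queries = sorted(set(grouped) | set(queries or []))
    rows = []
    for q in all_queries:
        hits = grouped.get(q)
        window = (evalue_window(sort_hits(hits)) if hits is not None
                  else HitWindow(q, blast.iloc[0:0], 0.0))
        native = native_descriptions.get(q) if native_descriptions is not None else None
        ann = infer_annotation(q, native, window, annotations,
                               subject_descriptions)
        rows.append({
            "query_id": q,
            "source": ann.source,
            "description": ann.description,
            "cc_terms": _render_terms(ann.go_terms["cellular_component"]),
            "mf_terms": _render_terms(ann.go_terms["molecular_function"]),
            "bp_terms": _render_terms(ann.go_terms["biological_process"]),
            "unannotated": ann.unannotated,
        })
    return pd.DataFrame(rows)


def transferred_go_frame(blast: pd.DataFrame,
                         annotations: pd.DataFrame) -> pd.DataFrame:
    """Long-form transferred GO table (query gene_id, go_id, domain, term).

    Used by the functional-summary stage: every window member's GO rows are
    copied onto the query, de-duplicated per (query, go_id).
    """
    out = []
    for q, hits in (blast.groupby("qseqid") if not blast.empty else []):
        window = evalue_window(sort_hits(hits))
        genes = {protein_to_gene(s) for s in window.subject_ids}
        sub = annotations[annotations["gene_id"].isin(genes)]
        if sub.empty:
            continue
        sub = sub.drop_duplicates(subset=["go_id"]).copy()
        sub["gene_id"] = str(q)
        out.append(sub)
    if not out:
        return annotations.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)
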