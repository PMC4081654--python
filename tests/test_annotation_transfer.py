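"""Hit sorting, the e-value window, LCS descriptions, and GO aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressmem.annotate import (HitWindow, aggregate_go, common_substrings,
                                evalue_window, infer_annotation,
                                native_is_absent, protein_to_gene, sort_hits)


def make_hits(rows):
    """rows: (qseqid, sseqid, evalue, length, pident)."""
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue",
                                     "length", "pident"])
    for col in ["mismatch", "gapopen", "qstart", "qend", "sstart", "send"]:
        df[col] = 1
    df["bitscore"] = 100.0
    return df


def brute_force_common_substrings(strings, k=3, min_len=4):
    """Independent oracle: enumerate every substring of the shortest string,
    keep those present in all, pick greedily by (length, first occurrence),
    masking occurrences between rounds."""
    import re
    masked = [re.sub(r"\s+", " ", s).strip().lower() for s in strings]
    if not masked or any(m == "" for m in masked):
        return []
    results = []
    for _ in range(k):
        host = min(masked, key=len)
        candidates = []
        for i in range(len(host)):
            for j in range(i + min_len, len(host) + 1):
                sub = host[i:j]
                if "\x00" in sub:
                    continue
                if all(sub in m for m in masked):
                    candidates.append((len(sub), -i, sub))
        if not candidates:
            break
        _, _, best = max(candidates)
        results.append(best)
        masked = [m.replace(best, "\x00" * len(best)) for m in masked]
    return results


class TestSortHits:
    def test_ascending_evalue_first(self):
        hits = make_hits([("q", "a", 1e-5, 100, 90.0),
                          ("q", "b", 1e-9, 100, 90.0)])
        assert sort_hits(hits)["sseqid"].tolist() == ["b", "a"]

    def test_equal_evalue_longer_alignment_first(self):
        hits = make_hits([("q", "a", 1e-5, 240, 90.0),
                          ("q", "b", 1e-5, 300, 90.0)])
        assert sort_hits(hits)["sseqid"].tolist() == ["b", "a"]

    def test_equal_evalue_and_length_higher_pid_first(self):
        hits = make_hits([("q", "a", 1e-5, 240, 80.0),
                          ("q", "b", 1e-5, 240, 95.0)])
        assert sort_hits(hits)["sseqid"].tolist() == ["b", "a"]

    def test_single_hit_is_itself(self):
        hits = make_hits([("q", "a", 1e-5, 100, 90.0)])
        assert sort_hits(hits)["sseqid"].tolist() == ["a"]


class TestEvalueWindow:
    def test_worked_example_upper_bound_inclusive(self):
        # best at 1e-63: the window reaches 1e-53 inclusive
        hits = sort_hits(make_hits([
            ("q", "a", 1e-63, 100, 90.0), ("q", "b", 1e-60, 100, 90.0),
            ("q", "c", 1e-53, 100, 90.0), ("q", "d", 1e-50, 100, 90.0)]))
        window = evalue_window(hits)
        assert window.subject_ids == ["a", "b", "c"]

    def test_single_hit_window_of_one(self):
        window = evalue_window(sort_hits(make_hits([("q", "a", 1e-5, 100, 90.0)])))
        assert len(window) == 1

    def test_zero_best_degenerate_rule(self):
        hits = sort_hits(make_hits([
            ("q", "a", 0.0, 100, 90.0), ("q", "b", 0.0, 90, 80.0),
            ("q", "c", 1e-180, 100, 90.0), ("q", "d", 1e-150, 100, 90.0)]))
        window = evalue_window(hits)
        assert window.subject_ids == ["a", "b", "c"]

    def test_empty_input_empty_window(self):
        assert len(evalue_window(make_hits([]))) == 0

    def test_contains_best_and_monotone_in_factor(self):
        rng = np.random.default_rng(3)
        hits = sort_hits(make_hits([
            ("q", f"s{i}", 10.0 ** -rng.uniform(5, 40), 100, 90.0)
            for i in range(12)]))
        wide = set(evalue_window(hits, factor=1e10).subject_ids)
        narrow = set(evalue_window(hits, factor=1e5).subject_ids)
        assert hits["sseqid"].iloc[0] in narrow
        assert narrow <= wide


class TestCommonSubstrings:
    def test_single_string_is_its_own_lcs(self):
        assert common_substrings(["protein kinase 1"]) == ["protein kinase 1"]

    def test_shared_stem_with_differing_suffix(self):
        out = common_substrings(["ABC transporter 1", "ABC transporter 2"])
        assert out[0] == "abc transporter"

    def test_disjoint_alphabets_empty(self):
        assert common_substrings(["xyz", "abc"]) == []

    def test_results_non_overlapping_within_host(self):
        out = common_substrings(["alpha beta gamma", "alpha delta gamma"],
                                trim_words=False)
        joined = "".join(out)
        host = "alpha beta gamma"
        for sub in out:
            assert sub in host
        assert len(joined) <= len(host)

    def test_matches_brute_force_on_fixed_triples(self):
        rng = np.random.default_rng(17)
        alphabet = "abcd "
        for _ in range(60):
            strings = ["".join(rng.choice(list(alphabet),
                                          size=rng.integers(4, 40)))
                       for _ in range(3)]
            assert (common_substrings(strings, trim_words=False)
                    == brute_force_common_substrings(strings))

    @given(st.lists(st.text(alphabet="abc ", min_size=1, max_size=25),
                    min_size=1, max_size=3))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_matches_brute_force_property(self, strings):
        assert (common_substrings(strings, trim_words=False)
                == brute_force_common_substrings(strings))


class TestAggregateGo:
    def _go(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "go_id", "domain", "term"])

    def _window(self, subjects):
        return HitWindow("q", make_hits([("q", s, 1e-10, 100, 90.0)
                                         for s in subjects]), 1.0)

    def test_two_terms_of_single_subject(self):
        go = self._go([("AT1G01010", "GO:1", "biological_process", "t1"),
                       ("AT1G01010", "GO:2", "biological_process", "t2")])
        out = aggregate_go(self._window(["AT1G01010.1"]), go)
        assert out["biological_process"] == [("t1", 1), ("t2", 1)]

    def test_shared_term_ranks_above_rare_term(self):
        go = self._go([(f"AT1G0{i}", f"GO:{i}", "molecular_function", "T")
                       for i in range(3)]
                      + [("AT1G00", "GO:9", "molecular_function", "U")])
        out = aggregate_go(self._window(["AT1G00.1", "AT1G01.1", "AT1G02.1"]), go)
        assert out["molecular_function"][0] == ("T", 3)

    def test_isoforms_counted_once_per_gene(self):
        go = self._go([("AT1G01010", "GO:1", "biological_process", "t")])
        out = aggregate_go(self._window(["AT1G01010.1", "AT1G01010.2"]), go)
        assert out["biological_process"] == [("t", 1)]

    def test_no_annotations_empty_lists(self):
        out = aggregate_go(self._window(["AT9G99999.1"]), self._go([]))
        assert all(v == [] for v in out.values())

    def test_counts_conserve_pairs(self):
        rng = np.random.default_rng(5)
        genes = [f"AT1G{i:05d}" for i in range(8)]
        rows = [(g, f"GO:{j}", "biological_process", f"term{j}")
                for g in genes for j in rng.choice(20, size=4, replace=False)]
        go = self._go(rows)
        window = self._window([g + ".1" for g in genes])
        out = aggregate_go(window, go, top_n=10 ** 6)
        assert sum(n for _, n in out["biological_process"]) == len(rows)


class TestInferAnnotation:
    GO = pd.DataFrame([("AT1G01010", "GO:1", "biological_process", "t")],
                      columns=["gene_id", "go_id", "domain", "term"])
    DESC = pd.Series({"AT1G01010": "asparagine synthase family protein",
                      "AT1G01020": "asparagine synthase-related protein"})

    def _window(self):
        return HitWindow("q", make_hits([("q", "AT1G01010.1", 1e-20, 100, 90.0),
                                         ("q", "AT1G01020.1", 1e-18, 90, 85.0)]),
                         1e-10)

    def test_native_description_kept_go_still_inferred(self):
        ann = infer_annotation("q", "asparagine synthase", self._window(),
                               self.GO, self.DESC)
        assert ann.source == "native"
        assert ann.description == "asparagine synthase"
        assert ann.go_terms["biological_process"] == [("t", 1)]

    @pytest.mark.parametrize("native", [None, "", "hypothetical protein",
                                        "putative protein", "Putative"])
    def test_placeholder_native_treated_as_absent(self, native):
        assert native_is_absent(native)
        ann = infer_annotation("q", native, self._window(), self.GO, self.DESC)
        assert ann.source == "inferred"
        assert "asparagine synthase" in ann.description

    def test_no_hits_flagged_unannotated(self):
        window = HitWindow("q", make_hits([]), 0.0)
        ann = infer_annotation("q", None, window, self.GO, self.DESC)
        assert ann.unannotated

    def test_isoform_suffix_stripping(self):
        assert protein_to_gene("AT1G01010.12") == "AT1G01010"
        assert protein_to_gene("GRMZM2G012345") == "GRMZM2G012345"
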