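"""Dialect fidelity of the tabular readers and writers."""

import math

import numpy as np
import pandas as pd
import pytest

from stressmem import io
from stressmem.errors import FormatError, ValidationError
from tests.conftest import make_diff_frame

CUFFDIFF_HEADER = ("test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\t"
                   "value_1\tvalue_2\tlog2(fold_change)\ttest_stat\tp_value\t"
                   "q_value\tsignificant\n")


def _cuffdiff_line(gene, v1, v2, fc, p, q, status="OK"):
    return (f"{gene}\t{gene}\t{gene}\tchr1:1-100\tW\tS1\t{status}\t"
            f"{v1}\t{v2}\t{fc}\t1.0\t{p}\t{q}\tyes\n")


class TestDiffTable:
    def test_header_only_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "empty.diff"
        path.write_text(CUFFDIFF_HEADER)
        out = io.read_diff_table(path, "S1_vs_W")
        assert len(out) == 0
        assert list(out.columns) == io.DIFF_COLUMNS

    def test_round_trip_is_identity(self, tmp_path):
        df = make_diff_frame([
            ("g1", 10.0, 40.0, 2.0, 0.001, 0.01, "OK"),
            ("g2", 5.0, 5.0, 0.0, 0.9, 0.95, "OK"),
            ("g3", 0.0, 0.0, 0.0, 1.0, 1.0, "NOTEST"),
        ])
        path = tmp_path / "t.diff"
        io.write_diff_table(df, path)
        back = io.read_diff_table(path, "S1_vs_W")
        pd.testing.assert_frame_equal(back[io.DIFF_COLUMNS],
                                      df[io.DIFF_COLUMNS])

    def test_zero_denominator_maps_to_signed_infinity(self, tmp_path):
        path = tmp_path / "inf.diff"
        path.write_text(CUFFDIFF_HEADER
                        + _cuffdiff_line("g1", 0.0, 8.0, "inf", 0.001, 0.01)
                        + _cuffdiff_line("g2", 8.0, 0.0, "-inf", 0.001, 0.01))
        out = io.read_diff_table(path, "S1_vs_W")
        assert out.loc[0, "log2_fc"] == math.inf
        assert out.loc[1, "log2_fc"] == -math.inf
        # sentinel survives a round trip (sign carries call information)
        io.write_diff_table(out, path)
        again = io.read_diff_table(path, "S1_vs_W")
        assert again.loc[0, "log2_fc"] == math.inf

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.diff"
        path.write_text("gene_id\tvalue_1\tvalue_2\tp_value\tq_value\tstatus\n")
        with pytest.raises(FormatError, match="log2"):
            io.read_diff_table(path, "S1_vs_W")

    def test_negative_fpkm_reports_row(self, tmp_path):
        path = tmp_path / "neg.diff"
        path.write_text(CUFFDIFF_HEADER
                        + _cuffdiff_line("g1", 1.0, 2.0, 1.0, 0.1, 0.2)
                        + _cuffdiff_line("g2", -1.0, 2.0, 1.0, 0.1, 0.2))
        with pytest.raises(ValidationError, match="row 2"):
            io.read_diff_table(path, "S1_vs_W")

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.diff"
        path.write_text(CUFFDIFF_HEADER
                        + _cuffdiff_line("g1", 1.0, 2.0, 1.0, 0.1, 0.2) * 2)
        with pytest.raises(ValidationError, match="g1"):
            io.read_diff_table(path, "S1_vs_W")

    def test_unknown_contrast_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="contrast"):
            io.read_diff_table(tmp_path / "x", "S2_vs_W")


class TestBlastTab:
    LINE = "g1\tAT1G01010.1\t88.5\t240\t27\t1\t1\t240\t1\t240\t1e-63\t500\n"

    def test_single_line_parses_key_columns(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.LINE)
        out = io.read_blast_tab(path)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["evalue"] == 1e-63
        assert row["pident"] == 88.5
        assert row["length"] == 240

    def test_empty_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(io.read_blast_tab(path)) == 0

    def test_zero_evalue_is_legal(self, tmp_path):
        path = tmp_path / "zero.tsv"
        path.write_text(self.LINE.replace("1e-63", "0.0"))
        assert io.read_blast_tab(path)["evalue"].iloc[0] == 0.0

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text(self.LINE + "g2\tAT1G01020.1\t50.0\n")
        with pytest.raises(FormatError, match="line 2"):
            io.read_blast_tab(path)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "rt.tsv"
        path.write_text(self.LINE * 1)
        df = io.read_blast_tab(path)
        io.write_blast_tab(df, path)
        pd.testing.assert_frame_equal(io.read_blast_tab(path), df)


class TestGoTsv:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "gene_id": ["AT1G01010", "AT1G01020"],
            "go_id": ["GO:0016020", "GO:0006412"],
            "domain": ["cellular_component", "biological_process"],
            "term": ["membrane", "translation"],
        })
        path = tmp_path / "go.tsv"
        io.write_go_tsv(df, path)
        pd.testing.assert_frame_equal(io.read_go_tsv(path), df)

    def test_duplicate_pair_collapsed_with_warning(self, tmp_path, caplog):
        path = tmp_path / "go.tsv"
        path.write_text("gene_id\tgo_id\tdomain\tterm\n"
                        "g1\tGO:0016020\tcellular_component\tmembrane\n"
                        "g1\tGO:0016020\tcellular_component\tmembrane\n")
        with caplog.at_level("WARNING"):
            out = io.read_go_tsv(path)
        assert len(out) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("variant", ["molecular function", "MF",
                                         "Molecular Function"])
    def test_domain_spelling_variants_normalized(self, tmp_path, variant):
        path = tmp_path / "go.tsv"
        path.write_text("gene_id\tgo_id\tdomain\tterm\n"
                        f"g1\tGO:0003700\t{variant}\ttranscription factor\n")
        assert io.read_go_tsv(path)["domain"].iloc[0] == "molecular_function"

    def test_unknown_domain_rejected(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("gene_id\tgo_id\tdomain\tterm\ng1\tGO:1\tbogus\tx\n")
        with pytest.raises(ValidationError, match="domain"):
            io.read_go_tsv(path)


class TestFpkmTable:
    def test_wide_round_trip(self, tmp_path, small_cohort):
        _, fpkm, _ = small_cohort
        path = tmp_path / "fpkm.tsv"
        io.write_fpkm_table(fpkm, path)
        back = io.read_fpkm_table(path)
        pd.testing.assert_frame_equal(back, fpkm.sort_index(axis=1))

    def test_long_layout_autodetected(self, tmp_path):
        long = pd.DataFrame({
            "gene_id": ["g1"] * 6,
            "condition": ["W", "W", "S1", "S1", "S3", "S3"],
            "replicate": [1, 2, 1, 2, 1, 2],
            "fpkm": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        path = tmp_path / "long.tsv"
        long.to_csv(path, sep="\t", index=False)
        wide = io.read_fpkm_table(path)
        assert list(wide.columns) == ["S1_1", "S1_2", "S3_1", "S3_2",
                                      "W_1", "W_2"]
        assert wide.loc["g1", "S3_2"] == 6.0

    def test_negative_fpkm_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("gene_id\tW_1\tW_2\tS1_1\tS1_2\tS3_1\tS3_2\n"
                        "g1\t1\t1\t-2\t1\t1\t1\n")
        with pytest.raises(ValidationError, match="negative"):
            io.read_fpkm_table(path)

    def test_unknown_sample_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tW_1\tS2_1\ng1\t1\t1\n")
        with pytest.raises(FormatError, match="S2_1"):
            io.read_fpkm_table(path)
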