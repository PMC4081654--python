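"""End-to-end orchestration: call -> classify -> annotate -> summarize ->
compare species, with a structured run manifest.

The config is a plain nested dict (typically loaded from YAML):

.. code-block:: yaml

    inputs:
      fpkm: data/fpkm.tsv            # or diff_s1 / diff_s3 external tables
      blast: data/blast_hits.tsv     # optional -> annotation stage
      go: data/go.tsv
      descriptions: data/descriptions.tsv
      native_descriptions: data/native.tsv
      homolog_map: data/homolog_map.tsv   # optional -> species comparison
      ref_classes: data/ref_classes.tsv
    criteria: {q_max: 0.05, min_abs_log2fc: 1.0, floor_percentile: 25}
    de: {epsilon: 1.0e-3, method: moderated, prior_df: 20}
    categories: null                 # path to a category YAML, or default

Stages never mutate one another's inputs; all intermediates are TSV/JSON
files with documented schemas.  Optional stages are skipped with a logged
notice when their inputs are absent.  On failure, a ``FAILED`` marker naming
the stage is left next to whatever partial outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import SignificanceCriteria, call_responses, simple_de_test
from .categories import build_matrix, heatmap_intensities, load_categories
from .conservation import conservation_verdicts, figure_tables
from .errors import StageError, ValidationError
from .io import (read_diff_table, read_descriptions_tsv, read_blast_tab,
                 read_fpkm_table, read_go_tsv, read_two_column_tsv,
                 write_diff_table)
from .memory import classify_genes, summarize_classes, write_summary_json
from .annotate import annotate_all, transferred_go_frame

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _criteria_from_config(config: dict) -> SignificanceCriteria:
    crit = config.get("criteria", {})
    return SignificanceCriteria(
        q_max=crit.get("q_max", 0.05),
        min_abs_log2fc=crit.get("min_abs_log2fc", 1.0),
        floor_percentile=crit.get("floor_percentile", 25.0),
    )


def run_all(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute every applicable stage and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": {k: _sha256(v) for k, v in inputs.items()
                          if v and Path(v).exists()},
        "stages": {},
        "outputs": [],
        "skipped": [],
    }
    current = "setup"
    try:
        # -- differential statistics ------------------------------------
        current = "call-de"
        t0 = time.perf_counter()
        crit = _criteria_from_config(config)
        de_cfg = config.get("de", {})
        if inputs.get("diff_s1") and inputs.get("diff_s3"):
            diff_s1 = read_diff_table(inputs["diff_s1"], "S1_vs_W")
            diff_s3 = read_diff_table(inputs["diff_s3"], "S3_vs_S1")
            fpkm = None
        elif inputs.get("fpkm"):
            fpkm = read_fpkm_table(inputs["fpkm"])
            kw = dict(epsilon=de_cfg.get("epsilon", 1e-3),
                      method=de_cfg.get("method", "moderated"),
                      prior_df=de_cfg.get("prior_df", 20.0))
            diff_s1 = simple_de_test(fpkm, "S1_vs_W", **kw)
            diff_s3 = simple_de_test(fpkm, "S3_vs_S1", **kw)
            for name, diff in (("diff_S1_vs_W.tsv", diff_s1),
                               ("diff_S3_vs_S1.tsv", diff_s3)):
                write_diff_table(diff, outdir / name)
                manifest["outputs"].append(name)
        else:
            raise ValidationError(
                "config must provide either inputs.fpkm or both "
                "inputs.diff_s1 and inputs.diff_s3")
        manifest["stages"]["call-de"] = time.perf_counter() - t0

        # -- tri-state calls + classification ---------------------------
        current = "classify"
        t0 = time.perf_counter()
        calls_s1 = call_responses(diff_s1, crit)
        calls_s3 = call_responses(diff_s3, crit)
        labels = classify_genes(calls_s1, calls_s3)
        labels.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        summary = summarize_classes(labels["class"])
        write_summary_json(summary, outdir / "summary.json")
        manifest["outputs"] += ["classification.tsv", "summary.json"]
        manifest["stages"]["classify"] = time.perf_counter() - t0

        # -- annotation transfer (optional) ------------------------------
        current = "annotate"
        t0 = time.perf_counter()
        go = None
        if inputs.get("go"):
            go = read_go_tsv(inputs["go"])
        if inputs.get("blast") and go is not None and inputs.get("descriptions"):
            blast = read_blast_tab(inputs["blast"])
            subject_desc = read_descriptions_tsv(inputs["descriptions"])
            native = (read_descriptions_tsv(inputs["native_descriptions"])
                      if inputs.get("native_descriptions") else pd.Series(dtype=str))
            annots = annotate_all(blast, native, subject_desc, go)
            annots.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
            manifest["outputs"].append("annotations.tsv")
            gene_go = transferred_go_frame(blast, go)
        else:
            gene_go = go
            if go is None:
                manifest["skipped"].append("annotate")
                logger.info("annotation stage skipped: no GO table configured")
        manifest["stages"]["annotate"] = time.perf_counter() - t0

        # -- functional summary (optional) -------------------------------
        current = "summarize"
        t0 = time.perf_counter()
        if gene_go is not None and not gene_go.empty:
            cats = load_categories(config.get("categories"))
            matrix = build_matrix(labels, gene_go, cats)
            matrix.render().rename_axis("category").to_csv(
                outdir / "category_matrix.tsv", sep="\t")
            heatmap_intensities(matrix.pct).rename_axis("category").to_csv(
                outdir / "category_intensities.tsv", sep="\t")
            manifest["outputs"] += ["category_matrix.tsv",
                                    "category_intensities.tsv"]
        else:
            manifest["skipped"].append("summarize")
            logger.info("functional summary skipped: no annotations available")
        manifest["stages"]["summarize"] = time.perf_counter() - t0

        # -- species comparison (optional) --------------------------------
        current = "compare-species"
        t0 = time.perf_counter()
        if inputs.get("homolog_map") and inputs.get("ref_classes"):
            homolog_map = read_two_column_tsv(inputs["homolog_map"],
                                              "maize_id", "ref_id")
            ref = read_two_column_tsv(inputs["ref_classes"], "gene_id", "class")
            ref_classes = ref.set_index("gene_id")["class"]
            memory_labels = labels[labels["memory_flag"]]
            maize_classes = memory_labels.set_index("gene_id")["class"]
            records = conservation_verdicts(maize_classes, homolog_map,
                                            ref_classes)
            records.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
            tables = figure_tables(records, homolog_map, ref_classes)
            with open(outdir / "conservation_summary.json", "w",
                      encoding="utf-8") as fh:
                json.dump(tables, fh, indent=2)
            manifest["outputs"] += ["conservation.tsv",
                                    "conservation_summary.json"]
        else:
            manifest["skipped"].append("compare-species")
            logger.info("species comparison skipped: homolog map or "
                        "reference classes not configured")
        manifest["stages"]["compare-species"] = time.perf_counter() - t0

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\ncause: {exc}\n",
                                       encoding="utf-8")
        raise StageError(current, exc) from exc

    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"].append("run_manifest.json")
    return manifest
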