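#!/usr/bin/env python
"""Nine-way memory classification and recovery against the planted truth.

Combines the two per-contrast call tables into the class partition, writes
the partition summary, and scores the called classes against the generator's
planted labels.
"""

import json
from pathlib import Path

import pandas as pd

from stressmem.memory import classify_genes, summarize_classes

DATA = Path("scratch/analysis_cohort")
RESULTS = Path("results")


def main():
    calls = {c: pd.read_csv(DATA / f"calls_{c}.tsv", sep="\t")
             for c in ("S1_vs_W", "S3_vs_S1")}
    labels = classify_genes(calls["S1_vs_W"], calls["S3_vs_S1"])
    labels.to_csv(DATA / "classification.tsv", sep="\t", index=False)
    summary = summarize_classes(labels["class"])

    truth = pd.read_csv(DATA / "truth_classes.tsv", sep="\t")
    merged = labels.merge(truth, on="gene_id", suffixes=("_called", "_planted"))
    recovery = (merged["class_called"] == merged["class_planted"]).mean()

    RESULTS.mkdir(exist_ok=True)
    payload = summary.to_dict()
    payload["planted_recovery_fraction"] = round(float(recovery), 4)
    with open(RESULTS / "03_class_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)

    print(f"classified {summary.total_genes} genes; "
          f"responders {summary.dehydration_response} "
          f"(memory {summary.memory_total}, "
          f"{100 * summary.memory_fraction:.1f}% of responders)")
    print(f"planted-class recovery: {100 * recovery:.2f}%")


if __name__ == "__main__":
    main()
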