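#!/usr/bin/env python
"""Cross-species memory conservation on the synthetic homolog map.

Partitions the mapped reference-species homologs by their own responses,
derives per-maize-gene conservation verdicts, and compares the recovered
same-type fraction with the generator's planted conservation fraction.
"""

import json
from pathlib import Path

import pandas as pd

from stressmem.conservation import conservation_verdicts, figure_tables
from stressmem.io import read_two_column_tsv

DATA = Path("scratch/analysis_cohort")
RESULTS = Path("results")


def main():
    labels = pd.read_csv(DATA / "classification.tsv", sep="\t")
    memory = labels[labels["memory_flag"]]
    maize_classes = memory.set_index("gene_id")["class"]
    hmap = read_two_column_tsv(DATA / "homolog_map.tsv", "maize_id", "ref_id")
    ref = read_two_column_tsv(DATA / "ref_classes.tsv", "gene_id", "class"
                              ).set_index("gene_id")["class"]
    # the map covers planted memory genes; restrict to genes also called
    # memory by the pipeline
    hmap = hmap[hmap["maize_id"].isin(maize_classes.index)]
    records = conservation_verdicts(maize_classes[
        maize_classes.index.isin(set(hmap["maize_id"]))], hmap, ref)
    tables = figure_tables(records, hmap, ref)

    truth = pd.read_csv(DATA / "truth_homology.tsv", sep="\t")
    planted = (truth["planted_outcome"] == "same").mean()
    recovered = (records["verdict"] == "memory_same_type").mean()
    tables["planted_same_type_fraction"] = round(float(planted), 4)
    tables["recovered_same_type_fraction"] = round(float(recovered), 4)

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "06_conservation_summary.json", "w") as fh:
        json.dump(tables, fh, indent=2)
    part = tables["homolog_partition"]
    print(f"homologs: {part['total_homologs']} "
          f"(no response {part['no_S1_response']}, "
          f"non-memory {part['responds_non_memory']}, "
          f"memory {part['responds_memory']})")
    print(f"same-type conservation: recovered {recovered:.3f} "
          f"vs planted {planted:.3f}")


if __name__ == "__main__":
    main()
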