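#!/usr/bin/env python
"""Class x functional-category matrix and heatmap intensities.

Builds the count/percentage matrix over the six reported classes from the
synthetic GO annotations, then maps percentages onto the capped linear
intensity ramp (saturation at 60%).
"""

from pathlib import Path

import pandas as pd

from stressmem.categories import build_matrix, heatmap_intensities
from stressmem.io import read_go_tsv

DATA = Path("scratch/analysis_cohort")
RESULTS = Path("results")


def main():
    labels = pd.read_csv(DATA / "classification.tsv", sep="\t")
    go = read_go_tsv(DATA / "go.tsv")
    matrix = build_matrix(labels, go)
    RESULTS.mkdir(exist_ok=True)
    matrix.render().rename_axis("category").to_csv(
        RESULTS / "05_category_matrix.tsv", sep="\t")
    heatmap_intensities(matrix.pct).round(3).rename_axis("category").to_csv(
        RESULTS / "05_category_intensities.tsv", sep="\t")
    top = matrix.counts.sum(axis=1).idxmax()
    print("class totals:", dict(matrix.class_totals))
    print(f"largest category across classes: {top}")


if __name__ == "__main__":
    main()
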