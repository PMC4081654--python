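#!/usr/bin/env python
"""Differential statistics and tri-state response calls for both contrasts.

Applies the moderated stand-in test to the simulated FPKM matrix, then the
three significance criteria (q <= 0.05, |log2FC| >= 1, 25th-percentile
expression floor).  Diff tables land in scratch/; the per-contrast call
tally in results/.
"""

from pathlib import Path

import pandas as pd

from stressmem.calling import call_responses, simple_de_test
from stressmem.io import read_fpkm_table, write_diff_table

DATA = Path("scratch/analysis_cohort")
RESULTS = Path("results")


def main():
    fpkm = read_fpkm_table(DATA / "fpkm.tsv")
    rows = []
    for contrast in ("S1_vs_W", "S3_vs_S1"):
        diff = simple_de_test(fpkm, contrast)
        write_diff_table(diff, DATA / f"diff_{contrast}.tsv")
        calls = call_responses(diff)
        calls.to_csv(DATA / f"calls_{contrast}.tsv", sep="\t", index=False)
        tally = calls["call"].value_counts()
        rows.append({"contrast": contrast,
                     "up": int(tally.get("up", 0)),
                     "down": int(tally.get("down", 0)),
                     "nochange": int(tally.get("nochange", 0))})
        print(f"{contrast}: {tally.get('up', 0)} up, {tally.get('down', 0)} "
              f"down of {len(calls)} genes")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "02_response_call_counts.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
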