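import numpy as np
import pandas as pd
import pytest

from stressmem.simulate import SimConfig, simulate_expression


def make_diff_frame(rows, contrast="S1_vs_W"):
    """Build a canonical diff frame from (gene, va, vb, fc, p, q, status)."""
    return pd.DataFrame(
        rows, columns=["gene_id", "value_a", "value_b", "log2_fc",
                       "p_value", "q_value", "status"]
    ).assign(contrast=contrast)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-gene synthetic cohort at the default study conditions."""
    cfg = SimConfig(seed=424242, n_genes=2000)
    fpkm, truth = simulate_expression(cfg)
    return cfg, fpkm, truth
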