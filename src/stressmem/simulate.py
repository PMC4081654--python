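"""Synthetic study generator with planted ground truth.

Emulates the repeated-dehydration study design: three conditions (watered W,
first stress S1, third stress S3) with two biological replicates each, a
log-normal baseline FPKM distribution, and per-gene condition-mean programs
planted according to a nine-class partition.  Default class proportions echo
the published partition (dehydration response ~5% of genes, ~40% of
responders showing memory); replicate noise is multiplicative log-normal
parameterized by a coefficient of variation, because the pipeline's criteria
operate on FPKM rather than on read counts.

Companion generators produce BLAST hit tables with planted e-value-window
membership, class-biased GO annotations and descriptions (to exercise the
category matrices and the common-substring synthesis), and homolog maps with
a planted conservation fraction.  Every generator is deterministic under a
fixed seed and writes truth tables alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (write_blast_tab, write_descriptions_tsv, write_fpkm_table,
                 write_go_tsv)
from .memory import (ALL_CLASSES, EE, EM, EP, ME, MEMORY_CLASSES,
                     NON_MEMORY_CLASSES, MM, MP, PE, PM, PP)

#: published per-class gene counts of the maize study (out of 39,635 genes);
#: the default class proportions are these counts over the total, with the
#: non-responsive class absorbing the remainder
STUDY_CLASS_COUNTS = {PP: 162, MM: 72, PM: 533, MP: 49,
                      PE: 941, ME: 305, EP: 1678, EM: 1246}
STUDY_TOTAL_GENES = 39635


def study_proportions() -> dict[str, float]:
    props = {c: n / STUDY_TOTAL_GENES for c, n in STUDY_CLASS_COUNTS.items()}
    props[EE] = 1.0 - sum(props.values())
    return props


def _default_enrichment() -> dict:
    # modest class-biased category draws so the matrices show planted contrast
    return {
        "RESP. Aba/Salt/Cold/Heat": {PP: 2.0, PM: 1.5},
        "Response to JA": {PM: 2.5},
        "Transcription factors": {PP: 1.2, PM: 1.2},
    }


def _default_category_rates() -> dict:
    # baseline per-category membership rates, echoing the published
    # distribution's order of magnitude (membrane functions dominate)
    return {
        "Membrane-associated": 0.28, "Chloroplast": 0.04,
        "Thylakoid membrane": 0.015, "RESP. Aba/Salt/Cold/Heat": 0.15,
        "Response to light": 0.05, "Response to JA": 0.03,
        "Response to SA": 0.03, "Response to Auxin": 0.012,
        "Response to ethylene": 0.035, "Response to GA": 0.02,
        "Lea": 0.01, "Ribosomal and protein synthesis": 0.012,
        "Protein degradation": 0.02, "Transcription factors": 0.10,
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    seed: int
    n_genes: int = STUDY_TOTAL_GENES
    class_proportions: dict = field(default_factory=study_proportions)
    #: natural-log mean / sd of the baseline FPKM law
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    #: planted |log2 fold change| range per responding transition
    effect_low: float = 1.5
    effect_high: float = 3.5
    replicate_cv: float = 0.2
    n_replicates: int = 2
    #: responder baselines are drawn above this quantile of the baseline law
    #: (stress-responsive genes are detectably expressed)
    responder_floor_quantile: float = 0.4
    # annotation model
    category_base_p: float = 0.05
    category_rates: dict = field(default_factory=_default_category_rates)
    enrichment: dict = field(default_factory=_default_enrichment)
    background_go_rate: float = 1.0
    # homology model
    conservation_fraction: float = 0.25
    p_different_memory: float = 0.15
    p_non_memory: float = 0.25
    p_no_response: float = 0.35
    extra_homolog_rate: float = 1.8
    # blast model
    blast_hits_mean: float = 3.0
    zero_best_p: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        hom = (self.conservation_fraction + self.p_different_memory
               + self.p_non_memory + self.p_no_response)
        if abs(hom - 1.0) > 1e-9:
            raise ValidationError(f"homolog outcome fractions sum to {hom}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


_EFFECT_SIGN_1 = {PP: 1, MM: -1, PM: 1, MP: -1, PE: 1, ME: -1,
                  EP: 0, EM: 0, EE: 0}
#: second-transition program: 'same' draws a fresh effect with the given
#: sign, 'revert' returns to the W level, 'none' stays at the S1 level
_SECOND_PROGRAM = {PP: ("draw", 1), MM: ("draw", -1),
                   PM: ("revert", 0), MP: ("revert", 0),
                   PE: ("none", 0), ME: ("none", 0),
                   EP: ("draw", 1), EM: ("draw", -1), EE: ("none", 0)}


def simulate_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the FPKM matrix and the per-gene truth table.

    Condition means follow the planted class program (e.g. a revised-response
    ``[+/-]`` gene has W = mu, S1 = mu * 2**d, S3 = mu); replicates multiply
    the mean by log-normal noise with unit mean and the configured CV.
    """
    rng = cfg.rng(1)
    classes = np.array(list(cfg.class_proportions))
    probs = np.array([cfg.class_proportions[c] for c in classes])
    planted = rng.choice(classes, size=cfg.n_genes, p=probs)

    mag1 = rng.uniform(cfg.effect_low, cfg.effect_high, cfg.n_genes)
    mag2 = rng.uniform(cfg.effect_low, cfg.effect_high, cfg.n_genes)
    sign1 = np.array([_EFFECT_SIGN_1[c] for c in planted])
    delta1 = sign1 * mag1
    delta2 = np.zeros(cfg.n_genes)
    for i, cls in enumerate(planted):
        mode, sign = _SECOND_PROGRAM[cls]
        if mode == "draw":
            delta2[i] = sign * mag2[i]
        elif mode == "revert":
            delta2[i] = -delta1[i]

    # Responders must be detectable: in each contrast they respond in, the
    # higher of the two contrasted condition means has to clear the
    # expression floor.  The binding sample shift is 0 or negative only for
    # repeatedly repressed programs (e.g. [-/-], whose second contrast
    # compares two already-repressed levels), which therefore need a higher
    # baseline - as in real data, where such genes are observable only when
    # expressed well above the detection floor to begin with.
    floor = float(np.exp(cfg.baseline_log_mean + cfg.baseline_log_sd
                         * _normal_ppf(cfg.responder_floor_quantile)))
    binding_shift = np.zeros(cfg.n_genes)
    for i, cls in enumerate(planted):
        shifts = []
        if cls[1] != "=":  # responds in S1 vs W
            shifts.append(max(0.0, delta1[i]))
        if cls[3] != "=":  # responds in S3 vs S1
            shifts.append(max(delta1[i], delta1[i] + delta2[i]))
        binding_shift[i] = min(shifts) if shifts else np.inf
    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    min_mu = np.where(np.isfinite(binding_shift),
                      floor * 2.0 ** -binding_shift, 0.0)
    low = mu <= min_mu
    while low.any():
        mu[low] = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                int(low.sum()))
        low = mu <= min_mu

    mu_w = mu
    mu_s1 = mu_w * 2.0 ** delta1
    mu_s3 = mu_s1 * 2.0 ** delta2

    sigma = float(np.sqrt(np.log1p(cfg.replicate_cv ** 2)))
    gene_ids = [f"ZmG{i:05d}" for i in range(cfg.n_genes)]
    data = {}
    for cond, means in (("W", mu_w), ("S1", mu_s1), ("S3", mu_s3)):
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, cfg.n_genes)
            data[f"{cond}_{rep}"] = means * noise
    fpkm = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame({
        "gene_id": gene_ids, "class": planted,
        "mu_w": mu_w, "mu_s1": mu_s1, "mu_s3": mu_s3,
        "delta1": delta1, "delta2": delta2,
    })
    return fpkm, truth


def _normal_ppf(q: float) -> float:
    from scipy.stats import norm
    return float(norm.ppf(q))


def simulate_blast_hits(cfg: SimConfig, query_ids=None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an outfmt-6 hit table with planted window membership.

    Per query the best hit's e-value is 10**-U(5, 80); further hits sit d
    decades above the best with d ~ U(0, 15), so each query mixes hits inside
    (d <= 10) and outside the window.  A small fraction of queries get a
    best e-value of exactly 0 to exercise the degenerate rule (extras there
    are planted against the absolute 1e-170 guard).
    """
    rng = cfg.rng(2)
    if query_ids is None:
        query_ids = [f"ZmQ{i:04d}" for i in range(200)]
    rows, truth_rows = [], []
    counter = 0
    for q in query_ids:
        n_hits = 1 + rng.poisson(cfg.blast_hits_mean)
        zero_best = rng.random() < cfg.zero_best_p
        best_exp = rng.uniform(5.0, 80.0)
        for j in range(n_hits):
            counter += 1
            sseqid = f"AT{rng.integers(1, 6)}G{counter:05d}.1"
            if zero_best:
                if j == 0:
                    evalue, in_window = 0.0, True
                else:
                    exp = rng.uniform(140.0, 200.0)
                    evalue, in_window = 10.0 ** -exp, exp >= 170.0
            else:
                d = 0.0 if j == 0 else rng.uniform(0.0, 15.0)
                evalue = 10.0 ** -(best_exp - d)
                in_window = d <= 10.0
            length = int(rng.integers(50, 500))
            pid = round(float(rng.uniform(30, 100)), 1)
            rows.append({
                "qseqid": q, "sseqid": sseqid, "pident": pid,
                "length": length,
                "mismatch": int(round(length * (1 - pid / 100))),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1, "qend": length, "sstart": 1, "send": length,
                "evalue": evalue,
                "bitscore": round(float(rng.uniform(50, 900)), 1),
            })
            truth_rows.append({"query_id": q, "subject_id": sseqid,
                               "evalue": evalue, "in_window": in_window})
    blast = pd.DataFrame(rows).sample(frac=1.0, random_state=int(cfg.seed)
                                      ).reset_index(drop=True)
    return blast, pd.DataFrame(truth_rows)


_DOMAIN_BY_CATEGORY = {
    "Membrane-associated": "cellular_component",
    "Chloroplast": "cellular_component",
    "Thylakoid membrane": "cellular_component",
    "Ribosomal and protein synthesis": "cellular_component",
    "Transcription factors": "molecular_function",
}

_TF_FAMILY_TERMS = [
    "ap2/erf transcription factor", "bhlh transcription factor",
    "bzip transcription factor", "homeobox transcription factor",
    "myb transcription factor", "zinc finger transcription factor",
    "nac domain transcription factor", "gras transcription factor",
    "heat shock transcription factor", "ccaat-binding transcription factor",
    "wrky transcription factor",
]


def simulate_annotations(cfg: SimConfig, truth: pd.DataFrame,
                         categories=None, stream: int = 3
                         ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Class-biased GO annotations and descriptions for the truth genes.

    Each gene joins each top-level category with its configured base rate
    times the per-class enrichment multiplier; transcription-factor members
    then draw one family term (so the family sub-table has content).
    Descriptions are built from shared category stems plus variable suffixes,
    which gives the common-substring synthesis something real to find.
    Returns the GO frame, the description Series, and the planted membership
    truth.  ``stream`` decouples independent draws under one seed.
    """
    from .categories import load_categories
    if categories is None:
        categories = load_categories()
    rng = cfg.rng(stream)
    parents = [c for c in categories if c.parent is None]
    go_rows, truth_rows, desc = [], [], {}
    go_id_of = {c.name: (sorted(c.go_ids)[0] if c.go_ids else
                         f"GO:9{abs(hash(c.name)) % 10 ** 6:06d}")
                for c in categories}
    for gene, cls in zip(truth["gene_id"], truth["class"]):
        member_terms = []
        for cat in parents:
            mult = cfg.enrichment.get(cat.name, {}).get(cls, 1.0)
            base = cfg.category_rates.get(cat.name, cfg.category_base_p)
            p = min(base * mult, 0.9)
            if rng.random() >= p:
                continue
            domain = _DOMAIN_BY_CATEGORY.get(cat.name, "biological_process")
            if cat.name == "Transcription factors":
                term = _TF_FAMILY_TERMS[int(rng.integers(len(_TF_FAMILY_TERMS)))]
            else:
                term = cat.term_substrings[0] if cat.term_substrings else cat.name.lower()
            go_rows.append({"gene_id": gene, "go_id": go_id_of[cat.name],
                            "domain": domain, "term": term})
            truth_rows.append({"gene_id": gene, "category": cat.name,
                               "class": cls})
            member_terms.append(term)
        for _ in range(int(rng.poisson(cfg.background_go_rate))):
            n = int(rng.integers(0, 10 ** 6))
            go_rows.append({"gene_id": gene, "go_id": f"GO:8{n:06d}",
                            "domain": "biological_process",
                            "term": f"uncharacterized process {n}"})
        if member_terms:
            suffix = int(rng.integers(1, 99))
            desc[gene] = f"putative {member_terms[0]} protein {suffix}"
        else:
            desc[gene] = "hypothetical protein"
    go = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "domain", "term"])
    go = go.drop_duplicates(subset=["gene_id", "go_id"]).reset_index(drop=True)
    return go, pd.Series(desc, name="description"), pd.DataFrame(truth_rows)


def simulate_homology(cfg: SimConfig, truth: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Homolog map and reference class labels with a planted conservation
    fraction.

    Each maize memory gene draws one primary homolog: with probability
    ``conservation_fraction`` it carries the same class symbol; otherwise a
    different memory class, a non-memory class, or a no-response class per
    the configured split.  Extra homologs (Poisson-many) never share the
    maize gene's class, so the planted same-type fraction stays identifiable.
    """
    rng = cfg.rng(4)
    memory = truth[truth["class"].isin(MEMORY_CLASSES)]
    outcomes = ("same", "different_memory", "non_memory", "no_response")
    probs = np.array([cfg.conservation_fraction, cfg.p_different_memory,
                      cfg.p_non_memory, cfg.p_no_response])
    no_response_classes = (EE, EP, EM)
    map_rows, ref_classes, truth_rows = [], {}, []
    counter = 0

    def _draw_class(outcome: str, maize_class: str) -> str:
        if outcome == "same":
            return maize_class
        if outcome == "different_memory":
            pool = [c for c in MEMORY_CLASSES if c != maize_class]
        elif outcome == "non_memory":
            pool = list(NON_MEMORY_CLASSES)
        else:
            pool = list(no_response_classes)
        return pool[int(rng.integers(len(pool)))]

    for gene, cls in zip(memory["gene_id"], memory["class"]):
        outcome = outcomes[int(rng.choice(len(outcomes), p=probs))]
        counter += 1
        ref = f"AT0G{counter:05d}"
        ref_classes[ref] = _draw_class(outcome, cls)
        map_rows.append({"maize_id": gene, "ref_id": ref})
        homolog_cls = [ref_classes[ref]]
        for _ in range(int(rng.poisson(cfg.extra_homolog_rate))):
            counter += 1
            extra = f"AT0G{counter:05d}"
            pool = [c for c in ALL_CLASSES if c != cls]
            ref_classes[extra] = pool[int(rng.integers(len(pool)))]
            map_rows.append({"maize_id": gene, "ref_id": extra})
            homolog_cls.append(ref_classes[extra])
        truth_rows.append({"gene_id": gene, "class": cls,
                           "planted_outcome": outcome,
                           "n_homologs": len(homolog_cls)})
    homolog_map = pd.DataFrame(map_rows, columns=["maize_id", "ref_id"])
    return (homolog_map, pd.Series(ref_classes, name="class"),
            pd.DataFrame(truth_rows))


def generate_all(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic input set + truth files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fpkm, truth = simulate_expression(cfg)
    paths["fpkm"] = outdir / "fpkm.tsv"
    write_fpkm_table(fpkm, paths["fpkm"])
    paths["truth_classes"] = outdir / "truth_classes.tsv"
    truth.to_csv(paths["truth_classes"], sep="\t", index=False)

    blast, truth_windows = simulate_blast_hits(cfg)
    paths["blast"] = outdir / "blast_hits.tsv"
    write_blast_tab(blast, paths["blast"])
    paths["truth_windows"] = outdir / "truth_windows.tsv"
    truth_windows.to_csv(paths["truth_windows"], sep="\t", index=False)

    # reference-side GO and descriptions for the BLAST subjects, so the
    # annotation-transfer stage has something to transfer
    from .annotate import protein_to_gene
    subjects = pd.DataFrame({
        "gene_id": sorted({protein_to_gene(s) for s in blast["sseqid"]})})
    subjects["class"] = EE
    subj_go, subj_desc, _ = simulate_annotations(cfg, subjects, stream=5)
    paths["subject_go"] = outdir / "subject_go.tsv"
    write_go_tsv(subj_go, paths["subject_go"])
    paths["subject_descriptions"] = outdir / "subject_descriptions.tsv"
    write_descriptions_tsv(subj_desc, paths["subject_descriptions"])

    go, desc, truth_cats = simulate_annotations(cfg, truth)
    paths["go"] = outdir / "go.tsv"
    write_go_tsv(go, paths["go"])
    paths["descriptions"] = outdir / "descriptions.tsv"
    write_descriptions_tsv(desc, paths["descriptions"])
    paths["truth_categories"] = outdir / "truth_categories.tsv"
    truth_cats.to_csv(paths["truth_categories"], sep="\t", index=False)

    homolog_map, ref_classes, truth_hom = simulate_homology(cfg, truth)
    paths["homolog_map"] = outdir / "homolog_map.tsv"
    homolog_map.to_csv(paths["homolog_map"], sep="\t", index=False)
    paths["ref_classes"] = outdir / "ref_classes.tsv"
    ref_classes.rename_axis("gene_id").reset_index().to_csv(
        paths["ref_classes"], sep="\t", index=False)
    paths["truth_homology"] = outdir / "truth_homology.tsv"
    truth_hom.to_csv(paths["truth_homology"], sep="\t", index=False)
    return paths
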