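"""Class x functional-category count/percentage matrices and heatmap scaling.

Rows are functional categories defined by GO-id sets and/or term substrings
(an editable YAML config; categories may overlap and a gene counts in every
category it matches).  Columns are the six reported response classes.  Each
cell holds a gene count and a within-class percentage,
``round(100 * count / class_total)`` with half-away-from-zero rounding;
sub-family rows (the transcription-factor families) use the parent
category's per-class count as denominator.  A class with zero genes renders
percentages as '-'.

Heatmap intensities map percentages linearly onto [0, 1] with saturation at
a cap (default 60%): black is 0% and full brightness is reached at the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .memory import SIX_CLASSES


@dataclass(frozen=True)
class CategoryDefinition:
    name: str
    go_ids: frozenset = frozenset()
    term_substrings: tuple = ()
    parent: str | None = None

    def __post_init__(self):
        if not self.go_ids and not self.term_substrings:
            raise ValidationError(f"category {self.name!r} has an empty predicate")


def load_categories(path=None) -> list[CategoryDefinition]:
    """Load category predicates from YAML (package default when no path)."""
    if path is None:
        text = (resources.files("stressmem") / "data" / "categories.yaml"
                ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    cats = []
    for entry in raw["categories"]:
        cats.append(CategoryDefinition(
            name=entry["name"],
            go_ids=frozenset(entry.get("go_ids", [])),
            term_substrings=tuple(s.lower() for s in entry.get("term_substrings", [])),
            parent=entry.get("parent"),
        ))
    names = [c.name for c in cats]
    for c in cats:
        if c.parent is not None and c.parent not in names:
            raise ValidationError(
                f"category {c.name!r} references unknown parent {c.parent!r}")
    return cats


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (matches the printed-table convention)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class CategoryMatrix:
    """counts / pct frames (rows categories, columns classes) + class totals."""

    counts: pd.DataFrame
    pct: pd.DataFrame
    class_totals: pd.Series
    denominators: pd.DataFrame = None

    def render(self) -> pd.DataFrame:
        """Human-readable '42 (26%)' cells, '-' where undefined or zero."""
        out = pd.DataFrame(index=self.counts.index, columns=self.counts.columns,
                           dtype=object)
        for cat in self.counts.index:
            for cls in self.counts.columns:
                n = int(self.counts.loc[cat, cls])
                p = self.pct.loc[cat, cls]
                out.loc[cat, cls] = ("-" if n == 0 else
                                     f"{n} (-)" if pd.isna(p) else
                                     f"{n} ({int(p)}%)")
        return out


def _gene_category_membership(annotations: pd.DataFrame,
                              categories: list[CategoryDefinition]
                              ) -> dict[str, set]:
    """category name -> set of gene ids matching the predicate."""
    terms_lower = annotations["term"].str.lower()
    members: dict[str, set] = {}
    for cat in categories:
        mask = annotations["go_id"].isin(cat.go_ids)
        for sub in cat.term_substrings:
            mask = mask | terms_lower.str.contains(sub, regex=False)
        members[cat.name] = set(annotations.loc[mask, "gene_id"])
    return members


def build_matrix(labels: pd.DataFrame, annotations: pd.DataFrame,
                 categories: list[CategoryDefinition] | None = None,
                 classes=SIX_CLASSES) -> CategoryMatrix:
    """Count genes per (category, class) and derive within-class percentages.

    ``labels`` is the classification frame (gene_id, class); ``annotations``
    the long GO table for the same genes (genes without annotation simply
    match nothing).  Sub-family percentages are taken over the parent
    category's count in the class; a zero denominator leaves pct undefined.
    """
    if categories is None:
        categories = load_categories()
    class_of = labels.set_index("gene_id")["class"]
    genes_by_class = {cls: set(class_of.index[class_of == cls]) for cls in classes}
    members = _gene_category_membership(annotations, categories)

    counts = pd.DataFrame(0, index=[c.name for c in categories],
                          columns=list(classes), dtype=int)
    for cat in categories:
        for cls in classes:
            counts.loc[cat.name, cls] = len(members[cat.name] & genes_by_class[cls])

    class_totals = pd.Series({cls: len(genes_by_class[cls]) for cls in classes},
                             name="class_total")
    denoms = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for cat in categories:
        if cat.parent is None:
            denoms.loc[cat.name] = class_totals.astype(float).to_numpy()
        else:
            denoms.loc[cat.name] = counts.loc[cat.parent].astype(float).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * counts.to_numpy() / denoms.to_numpy()
    pct = pd.DataFrame(round_half_away(ratio), index=counts.index,
                       columns=counts.columns)
    pct = pct.where(denoms > 0)  # undefined where the denominator is 0
    return CategoryMatrix(counts=counts, pct=pct, class_totals=class_totals,
                          denominators=denoms)


def heatmap_intensities(pct: pd.DataFrame | np.ndarray,
                        cap: float = 60.0) -> pd.DataFrame | np.ndarray:
    """Linear intensity ramp: 0% -> 0.0, ``cap``% and above -> 1.0.

    Undefined percentages (zero-denominator cells) render black (0.0).
    """
    if cap <= 0:
        raise ValidationError("cap must be positive")
    values = pct.to_numpy(dtype=float) if isinstance(pct, pd.DataFrame) else \
        np.asarray(pct, dtype=float)
    if np.nanmin(values, initial=0) < 0:
        raise ValidationError("percentages must be non-negative")
    out = np.minimum(np.nan_to_num(values, nan=0.0), cap) / cap
    if isinstance(pct, pd.DataFrame):
        return pd.DataFrame(out, index=pct.index, columns=pct.columns)
    return out


def pairwise_species_matrix(matrix_a: CategoryMatrix, matrix_b: CategoryMatrix,
                            names: tuple[str, str] = ("ZM", "AT"),
                            cap: float = 60.0):
    """Interleave two species' matrices class-by-class for joint heatmaps.

    Both inputs must share the category row set (mismatch raises, listing the
    missing rows).  Returns (pct frame, intensity frame) whose columns are a
    (class, species) MultiIndex in class-major order.
    """
    rows_a, rows_b = set(matrix_a.pct.index), set(matrix_b.pct.index)
    if rows_a != rows_b:
        raise ValidationError(
            f"category rows differ: only in first {sorted(rows_a - rows_b)}, "
            f"only in second {sorted(rows_b - rows_a)}")
    cols = pd.MultiIndex.from_tuples(
        [(cls, sp) for cls in matrix_a.pct.columns for sp in names],
        names=["class", "species"])
    pct = pd.DataFrame(index=matrix_a.pct.index, columns=cols, dtype=float)
    for cls in matrix_a.pct.columns:
        pct[(cls, names[0])] = matrix_a.pct[cls]
        pct[(cls, names[1])] = matrix_b.pct.loc[matrix_a.pct.index, cls]
    return pct, heatmap_intensities(pct, cap=cap)
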