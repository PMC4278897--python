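"""Six-category tissue-specificity classification of a gene x tissue panel.

Every gene is assigned exactly one category relative to a chosen target
tissue, using a detection cutoff (default 1 FPKM, roughly one mRNA per
cell) and a fold threshold (default 5):

``not_detected``
    target FPKM below the cutoff.
``tissue_enriched``
    target FPKM at least ``fold`` times that of every other tissue.
``group_enriched``
    a group of ``group_min``..``group_max`` tissues (default 2-7)
    containing the target all lie at least ``fold`` above every tissue
    outside the group.
``tissue_enhanced``
    target FPKM at least ``fold`` times the mean FPKM over all tissues
    (target included).
``expressed_in_all``
    detected (FPKM >= cutoff) in every tissue.
``mixed``
    detected in the target but in none of the above categories.

The three fold-based categories are together termed "elevated". The
precedence above places the elevated categories ahead of
``expressed_in_all`` so that an enhanced gene detected in every tissue is
still counted as elevated. Each gene also receives a tissue-specific
score: target FPKM divided by the maximum FPKM in any other tissue
(``inf`` when no other tissue expresses the gene, ``nan`` when the gene is
silent everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = (
    "not_detected",
    "tissue_enriched",
    "group_enriched",
    "tissue_enhanced",
    "expressed_in_all",
    "mixed",
)

ELEVATED = ("tissue_enriched", "group_enriched", "tissue_enhanced")


@dataclass(frozen=True)
class SpecificityParams:
    """Thresholds of the specificity classification.

    Attributes
    ----------
    target_tissue
        Tissue the categories are defined relative to.
    detection_cutoff
        FPKM below which a gene counts as not detected in a tissue.
    fold
        Enrichment fold threshold; comparisons are inclusive (>=).
    group_min, group_max
        Allowed size range of a group-enriched tissue set (target included).
    """

    target_tissue: str
    detection_cutoff: float = 1.0
    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7

    def __post_init__(self) -> None:
        if self.detection_cutoff <= 0:
            raise ValueError("detection_cutoff must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if not (2 <= self.group_min <= self.group_max):
            raise ValueError("need 2 <= group_min <= group_max")


@dataclass
class GeneClassification:
    """Category call for one gene, with its score and supporting detail."""

    gene_id: str
    category: str
    score: float
    group: tuple[str, ...] = field(default_factory=tuple)
    n_detected: int = 0


def specificity_score(row: pd.Series, target: str) -> float:
    """Tissue-specific score: target FPKM over the max FPKM elsewhere.

    Returns ``inf`` when the target is positive but every other tissue is
    zero, 0.0 when the target is zero and some other tissue is positive,
    and ``nan`` when the gene is zero everywhere.
    """
    if target not in row.index:
        raise KeyError(f"target tissue {target!r} not in row")
    t = float(row[target])
    others = row.drop(target).to_numpy(dtype=float)
    if others.size == 0:
        raise ValueError("need at least one non-target tissue")
    m = float(others.max())
    if m > 0:
        return t / m
    return np.inf if t > 0 else np.nan


def find_enriched_group(
    row: pd.Series, params: SpecificityParams
) -> tuple[str, ...] | None:
    """Smallest tissue set containing the target whose members all lie at
    least ``fold`` above every tissue outside the set.

    Implemented as a sorted-prefix scan: a qualifying group must contain
    every tissue expressed above its own minimum, so only prefixes of the
    FPKM-descending order can qualify. Ties are broken by tissue label so
    the result is deterministic. Returns the member tissues sorted by
    label, or ``None`` if no group of allowed size exists.
    """
    labels = list(row.index)
    values = row.to_numpy(dtype=float)
    target_idx = labels.index(params.target_tissue)
    order = sorted(range(len(labels)), key=lambda i: (-values[i], labels[i]))
    n = len(labels)
    for k in range(params.group_min, min(params.group_max, n) + 1):
        prefix = order[:k]
        if target_idx not in prefix:
            continue
        outside = values[order[k:]]
        max_outside = outside.max() if outside.size else 0.0
        if values[prefix].min() >= params.fold * max_outside:
            return tuple(sorted(labels[i] for i in prefix))
    return None


def classify_gene(row: pd.Series, params: SpecificityParams) -> GeneClassification:
    """Classify a single gene's per-tissue FPKM row."""
    if params.target_tissue not in row.index:
        raise KeyError(f"target tissue {params.target_tissue!r} not in row")
    cutoff, fold = params.detection_cutoff, params.fold
    values = row.to_numpy(dtype=float)
    t = float(row[params.target_tissue])
    others = row.drop(params.target_tissue).to_numpy(dtype=float)
    n_detected = int((values >= cutoff).sum())
    score = specificity_score(row, params.target_tissue)

    group: tuple[str, ...] = ()
    if t < cutoff:
        category = "not_detected"
    elif t >= fold * others.max():
        category = "tissue_enriched"
    elif (found := find_enriched_group(row, params)) is not None:
        category = "group_enriched"
        group = found
    elif t >= fold * values.mean():
        category = "tissue_enhanced"
    elif n_detected == len(values):
        category = "expressed_in_all"
    else:
        category = "mixed"
    return GeneClassification(str(row.name), category, score, group, n_detected)


def classify_all(
    profile: pd.DataFrame, params: SpecificityParams
) -> pd.DataFrame:
    """Classify every gene of a tissue profile.

    Returns a DataFrame indexed by gene with columns ``category``,
    ``score``, ``group`` (tuple of tissues, nonempty only for
    group-enriched genes) and ``n_detected``. The heavy comparisons are
    vectorised; the group search only runs on genes that survive the
    not-detected and tissue-enriched rules.
    """
    if params.target_tissue not in profile.columns:
        raise KeyError(
            f"target tissue {params.target_tissue!r} not in profile")
    cutoff, fold = params.detection_cutoff, params.fold
    values = profile.to_numpy(dtype=float)
    n_genes, n_tissues = values.shape
    tcol = profile.columns.get_loc(params.target_tissue)
    t = values[:, tcol]
    others = np.delete(values, tcol, axis=1)
    max_others = others.max(axis=1)
    mean_all = values.mean(axis=1)
    n_detected = (values >= cutoff).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(max_others > 0, t / max_others,
                         np.where(t > 0, np.inf, np.nan))

    category = np.full(n_genes, "", dtype=object)
    groups: list[tuple[str, ...]] = [()] * n_genes

    nd = t < cutoff
    enr = ~nd & (t >= fold * max_others)
    category[nd] = "not_detected"
    category[enr] = "tissue_enriched"

    undecided = np.nonzero(~nd & ~enr)[0]
    for i in undecided:
        found = find_enriched_group(profile.iloc[i], params)
        if found is not None:
            category[i] = "group_enriched"
            groups[i] = found
    open_mask = category == ""
    enh = open_mask & (t >= fold * mean_all)
    category[enh] = "tissue_enhanced"
    open_mask = category == ""
    all_det = open_mask & (n_detected == n_tissues)
    category[all_det] = "expressed_in_all"
    category[category == ""] = "mixed"

    return pd.DataFrame(
        {
            "category": pd.Categorical(category, categories=CATEGORIES),
            "score": score,
            "group": groups,
            "n_detected": n_detected,
        },
        index=profile.index,
    )


def category_census(classes: pd.DataFrame) -> dict[str, int]:
    """Gene counts per category plus the derived ``elevated`` total."""
    counts = classes["category"].value_counts()
    census = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    census["elevated"] = sum(census[c] for c in ELEVATED)
    return census


def elevated_genes(classes: pd.DataFrame) -> pd.Index:
    """Genes in any of the three elevated categories."""
    return classes.index[classes["category"].isin(ELEVATED)]


def format_classes(classes: pd.DataFrame) -> pd.DataFrame:
    """Render a classification table for TSV output: scores as ``inf`` /
    ``NA`` literals, groups semicolon-joined."""
    out = classes.copy()
    out["score"] = [
        "NA" if np.isnan(s) else ("inf" if np.isinf(s) else f"{s:.6g}")
        for s in classes["score"]
    ]
    out["group"] = [";".join(g) for g in classes["group"]]
    return out
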