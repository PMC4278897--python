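"""Decomposition of a tissue's mRNA pool by specificity category.

The mRNA pool of a tissue is its summed FPKM over all genes; category
fractions say how much of the transcriptional output each specificity
class carries. In a secretory organ like the pancreas a tiny fraction of
genes (the elevated ones) can dominate the pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tissuespec.specificity_classifier import CATEGORIES, ELEVATED


@dataclass
class CompositionSummary:
    """Per-category gene counts and mRNA-pool fractions for one tissue.

    ``fractions`` sum to 1 over the six categories whenever the tissue
    expresses anything. ``dynamic_range`` is (min detected FPKM, max FPKM,
    ratio), or ``None`` when no gene is detected.
    """

    target: str
    counts: dict[str, int]
    fractions: dict[str, float]
    expressed_fraction: float
    dynamic_range: tuple[float, float, float] | None

    @property
    def elevated_fraction(self) -> float:
        return sum(self.fractions[c] for c in ELEVATED)

    @property
    def elevated_count(self) -> int:
        return sum(self.counts[c] for c in ELEVATED)


def expressed_fraction(
    profile: pd.DataFrame, target: str, cutoff: float = 1.0
) -> float:
    """Share of all genes with target-tissue FPKM at or above the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    col = profile[target].to_numpy(dtype=float)
    return float((col >= cutoff).sum() / col.size)


def dynamic_range(
    profile: pd.DataFrame, target: str, cutoff: float = 1.0
) -> tuple[float, float, float]:
    """(min detected FPKM, max FPKM, ratio) of the target tissue column."""
    col = profile[target].to_numpy(dtype=float)
    detected = col[col >= cutoff]
    if detected.size == 0:
        raise ValueError(f"no detected genes in tissue {target!r}")
    lo, hi = float(detected.min()), float(col.max())
    return lo, hi, hi / lo


def mrna_pool_fractions(
    profile: pd.DataFrame,
    classes: pd.DataFrame,
    target: str,
    cutoff: float = 1.0,
) -> CompositionSummary:
    """Decompose the target tissue's mRNA pool by specificity category.

    A category's fraction is the summed target-tissue FPKM of its genes
    divided by the summed FPKM of all genes. Counts replicate the census.
    """
    missing = profile.index.difference(classes.index)
    if len(missing) > 0:
        raise ValueError(
            f"classification missing {len(missing)} genes, e.g. {missing[0]!r}")
    col = profile[target]
    total = float(col.sum())
    cats = classes.loc[profile.index, "category"]
    counts, fractions = {}, {}
    for c in CATEGORIES:
        in_c = cats == c
        counts[c] = int(in_c.sum())
        fractions[c] = float(col[in_c.to_numpy()].sum() / total) if total > 0 else 0.0
    try:
        rng = dynamic_range(profile, target, cutoff)
    except ValueError:
        rng = None
    return CompositionSummary(
        target=target,
        counts=counts,
        fractions=fractions,
        expressed_fraction=expressed_fraction(profile, target, cutoff),
        dynamic_range=rng,
    )


def composition_table(summary: CompositionSummary) -> pd.DataFrame:
    """Tabular form of a composition summary for TSV export."""
    rows = [
        {"category": c, "n_genes": summary.counts[c],
         "mrna_fraction": summary.fractions[c]}
        for c in CATEGORIES
    ]
    rows.append({"category": "elevated", "n_genes": summary.elevated_count,
                 "mrna_fraction": summary.elevated_fraction})
    return pd.DataFrame(rows)
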