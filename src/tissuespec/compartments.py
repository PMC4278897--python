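"""Compartment-enriched genes from isolate preparations.

Whole-organ RNA-seq dilutes transcripts of rare cell populations (islets
of Langerhans are ~1-2% of pancreatic mass), so genes elevated in an
isolated compartment can be invisible in whole tissue. Here each isolate
profile (e.g. purified islet or exocrine preparations, replicate-averaged
like any tissue) is appended to the comparison panel as if it were a
tissue of its own and classified with the standard scheme; the resulting
elevated sets are intersected with the whole-tissue elevated set and laid
out as a three-set Venn partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tissuespec.specificity_classifier import (
    SpecificityParams,
    classify_all,
    elevated_genes,
)

VENN_REGIONS = ("a", "b", "c", "ab", "ac", "bc", "abc")


@dataclass
class CompartmentResult:
    """Elevated gene sets per compartment and their Venn decomposition.

    ``venn`` maps the seven exclusive regions (a = islet, b = exocrine,
    c = whole tissue) to gene counts; ``isolate_only`` holds genes
    elevated in an isolate but not in the whole tissue.
    """

    islet_elevated: frozenset[str]
    exocrine_elevated: frozenset[str]
    whole_elevated: frozenset[str]
    venn: dict[str, int] = field(default_factory=dict)
    isolate_only: frozenset[str] = frozenset()

    def isolate_status(self) -> dict[str, str]:
        """Per-gene annotation of which isolate(s) it is elevated in."""
        status: dict[str, str] = {}
        for gene in sorted(self.islet_elevated | self.exocrine_elevated):
            tags = []
            if gene in self.islet_elevated:
                tags.append("islet enriched")
            if gene in self.exocrine_elevated:
                tags.append("exocrine enriched")
            status[gene] = "; ".join(tags)
        return status


def venn_partition(a: set, b: set, c: set) -> dict[str, int]:
    """Counts of the seven exclusive regions of a three-set Venn diagram."""
    a, b, c = set(a), set(b), set(c)
    return {
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def isolate_enrichment(
    tissue_profile: pd.DataFrame,
    isolate_profile: pd.DataFrame,
    params: SpecificityParams,
    exclude_parent: bool = True,
) -> CompartmentResult:
    """Find genes elevated in isolate compartments versus the tissue panel.

    Each isolate column is classified as the target against the whole-
    tissue panel; with ``exclude_parent`` the parent tissue
    (``params.target_tissue``) is dropped from the comparison so its high
    shared transcripts cannot mask isolate enrichment. The whole-tissue
    elevated set comes from the standard run on the unmodified panel.

    ``isolate_profile`` columns are compartment names; ``islet`` and
    ``exocrine`` feed the named result fields.
    """
    overlap_diff = tissue_profile.index.symmetric_difference(
        isolate_profile.index)
    if len(overlap_diff) > 0:
        raise ValueError(
            f"gene sets differ by {len(overlap_diff)} genes between tissue "
            "and isolate profiles")
    shared = [c for c in isolate_profile.columns if c in tissue_profile.columns]
    if shared:
        raise ValueError(f"isolate columns also in tissue panel: {shared}")

    comparison = tissue_profile
    if exclude_parent:
        comparison = tissue_profile.drop(columns=params.target_tissue)

    elevated: dict[str, frozenset[str]] = {}
    for compartment in isolate_profile.columns:
        panel = pd.concat([isolate_profile[[compartment]], comparison], axis=1)
        iso_params = SpecificityParams(
            target_tissue=compartment,
            detection_cutoff=params.detection_cutoff,
            fold=params.fold,
            group_min=params.group_min,
            group_max=params.group_max,
        )
        elevated[compartment] = frozenset(
            elevated_genes(classify_all(panel, iso_params)))

    whole = frozenset(elevated_genes(classify_all(tissue_profile, params)))
    islet = elevated.get("islet", frozenset())
    exocrine = elevated.get("exocrine", frozenset())
    return CompartmentResult(
        islet_elevated=islet,
        exocrine_elevated=exocrine,
        whole_elevated=whole,
        venn=venn_partition(set(islet), set(exocrine), set(whole)),
        isolate_only=frozenset((islet | exocrine) - whole),
    )
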