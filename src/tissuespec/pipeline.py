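"""End-to-end orchestration: validate, average, classify, compose,
correlate, compartments, network — one config, one call, one manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tissuespec.compartments import VENN_REGIONS, isolate_enrichment
from tissuespec.composition import composition_table, mrna_pool_fractions
from tissuespec.expression_io import (
    average_replicates,
    read_annotation,
    read_fpkm_table,
    validate_annotation,
)
from tissuespec.sharing_network import build_sharing_network
from tissuespec.similarity import spearman_matrix
from tissuespec.specificity_classifier import (
    SpecificityParams,
    category_census,
    classify_all,
    format_classes,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of a full pipeline run."""

    matrix: str
    annotation: str
    outdir: str
    target_tissue: str
    detection_cutoff: float = 1.0
    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7
    similarity_filter: str = "all"
    exclude_parent: bool = True
    include_enriched_in_network: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def params(self) -> SpecificityParams:
        return SpecificityParams(
            target_tissue=self.target_tissue,
            detection_cutoff=self.detection_cutoff,
            fold=self.fold,
            group_min=self.group_min,
            group_max=self.group_max,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage and write its outputs plus a manifest.

    Stage outputs equal what the individual library calls produce; the
    manifest (JSON) records parameters, package version and input
    checksums so a run can be reproduced exactly. Returns a dict of
    output paths plus the in-memory stage results.
    """
    for path in (config.matrix, config.annotation):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params()

    matrix = read_fpkm_table(config.matrix)
    annotation = read_annotation(config.annotation)
    validate_annotation(annotation, matrix)
    logger.info("loaded %d genes x %d samples", *matrix.shape)

    profile = average_replicates(matrix, annotation, "whole")
    classes = classify_all(profile, params)
    census = category_census(classes)
    logger.info("census: %s", census)
    logger.debug("per-category: %s",
                 {k: v for k, v in census.items() if k != "elevated"})
    format_classes(classes).to_csv(outdir / "classifications.tsv", sep="\t",
                                   index_label="gene")

    summary = mrna_pool_fractions(profile, classes, params.target_tissue,
                                  params.detection_cutoff)
    comp = composition_table(summary)
    with open(outdir / "composition.tsv", "w") as fh:
        comp.to_csv(fh, sep="\t", index=False)
        fh.write(f"# expressed_fraction\t{summary.expressed_fraction:.6g}\n")
        if summary.dynamic_range:
            lo, hi, ratio = summary.dynamic_range
            fh.write(f"# dynamic_range\t{lo:.6g}\t{hi:.6g}\t{ratio:.6g}\n")

    corr = spearman_matrix(matrix, config.similarity_filter,
                           params.detection_cutoff)
    corr.to_csv(outdir / "correlations.tsv", sep="\t")

    result: dict = {
        "outdir": str(outdir),
        "census": census,
        "summary": summary,
        "classes": classes,
        "correlations": corr,
    }

    isolates = annotation[annotation["compartment"] != "whole"]
    if len(isolates) > 0:
        iso_profile = average_replicates(
            matrix[isolates.index],
            isolates.assign(tissue=isolates["compartment"]))
        compartments = isolate_enrichment(profile, iso_profile, params,
                                          config.exclude_parent)
        pd.DataFrame(
            {"region": VENN_REGIONS,
             "count": [compartments.venn[k] for k in VENN_REGIONS]},
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        status = compartments.isolate_status()
        pd.DataFrame(
            {"gene": list(status), "isolate_status": list(status.values())}
        ).to_csv(outdir / "compartments.tsv", sep="\t", index=False)
        result["compartments"] = compartments

    network = build_sharing_network(classes, params.target_tissue,
                                    config.include_enriched_in_network)
    network.nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    network.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    result["network"] = network

    from tissuespec import __version__ as version  # deferred: circular import

    manifest = {
        "version": version,
        "parameters": asdict(config),
        "inputs": {
            "matrix": {"path": str(config.matrix),
                       "sha256": _sha256(config.matrix)},
            "annotation": {"path": str(config.annotation),
                           "sha256": _sha256(config.annotation)},
        },
        "census": census,
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result["manifest"] = manifest
    return result
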