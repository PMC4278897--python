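"""Synthetic FPKM panels with planted specificity structure.

The generator emulates a multi-tissue bulk RNA-seq FPKM panel: a fixed
roster of tissues (27 by default) with 1-4 replicate samples each,
log-normal baseline expression spanning several orders of magnitude,
genes planted to satisfy the defining inequality of each specificity
category with a configurable safety margin (stricter than the
classification fold, so calls survive moderate noise), multiplicative
log-normal replicate noise, and in-lane barcode leakage mimicking index
misassignment on multiplexed sequencing lanes (~0.1% of reads showing up
under a lanemate's barcode).

Every run returns the ground-truth labels alongside the matrix, so the
classifier's recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tissuespec.expression_io import validate_annotation, validate_matrix
from tissuespec.specificity_classifier import CATEGORIES, ELEVATED, SpecificityParams

TISSUES = (
    "pancreas", "adipose", "adrenal gland", "appendix", "bone marrow",
    "brain", "colon", "duodenum", "endometrium", "esophagus", "gallbladder",
    "heart", "kidney", "liver", "lung", "lymph node", "ovary", "placenta",
    "prostate", "salivary gland", "skin", "small intestine", "spleen",
    "stomach", "testis", "thyroid", "urinary bladder",
)

DEFAULT_COUNTS = {
    "not_detected": 600,
    "tissue_enriched": 100,
    "group_enriched": 100,
    "tissue_enhanced": 100,
    "expressed_in_all": 700,
    "mixed": 400,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic FPKM panel.

    Attributes
    ----------
    n_tissues
        Number of tissues in the panel (target included).
    counts
        Genes to plant per specificity category.
    baseline_log_mu, baseline_log_sigma
        Natural-log location/scale of the log-normal baseline FPKM draw;
        the defaults give a panel-wide dynamic range of roughly five
        orders of magnitude.
    margin
        Fold factor the planted inequalities hold with, before noise;
        must exceed ``fold`` so that noisy replicates stay classifiable.
    noise_cv
        Coefficient of variation of the multiplicative replicate noise.
    leakage_rate
        In-lane barcode leakage rate r: each sample keeps (1 - r) of its
        signal and the leaked r is split equally among lanemates.
    replicate_range
        Inclusive (low, high) range replicate counts are drawn from;
        the target tissue always gets ``target_replicates``.
    lane_size
        Samples multiplexed per sequencing lane.
    """

    n_tissues: int = 27
    target_tissue: str = "pancreas"
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    baseline_log_mu: float = 0.5
    baseline_log_sigma: float = 2.0
    detection_cutoff: float = 1.0
    fold: float = 5.0
    margin: float = 8.0
    group_min: int = 2
    group_max: int = 7
    replicate_range: tuple[int, int] = (1, 4)
    target_replicates: int = 2
    noise_cv: float = 0.05
    leakage_rate: float = 0.001
    lane_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValueError("need at least two tissues")
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in counts: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("category counts must be >= 0")
        if sum(self.counts.values()) == 0:
            raise ValueError("need at least one gene")
        if self.margin <= self.fold:
            raise ValueError("margin must exceed the classification fold")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.leakage_rate < 1:
            raise ValueError("leakage_rate must be in [0, 1)")
        needs_crowd = (self.counts.get("tissue_enhanced", 0)
                       or self.counts.get("mixed", 0))
        if needs_crowd and self.n_tissues < self.group_max + 5:
            raise ValueError(
                "planting enhanced/mixed genes needs n_tissues >= group_max + 5")
        if self.counts.get("tissue_enhanced", 0) and self.n_tissues <= self.margin + 2:
            raise ValueError(
                "planting enhanced genes needs n_tissues > margin + 2")

    @property
    def tissues(self) -> list[str]:
        extra = [f"tissue_{i:02d}" for i in range(len(TISSUES) + 1,
                                                  self.n_tissues + 1)]
        names = list(TISSUES[: self.n_tissues]) + extra
        if self.target_tissue not in names:
            names[0] = self.target_tissue
        return names

    def params(self) -> SpecificityParams:
        """Classification parameters matching the planted structure."""
        return SpecificityParams(
            target_tissue=self.target_tissue,
            detection_cutoff=self.detection_cutoff,
            fold=self.fold,
            group_min=self.group_min,
            group_max=self.group_max,
        )


def _baseline(rng: np.random.Generator, config: SimulationConfig, n: int):
    return np.exp(rng.normal(config.baseline_log_mu,
                             config.baseline_log_sigma, n))


def _plant_row(rng, config: SimulationConfig, category: str,
               tissues: list[str]):
    """Per-tissue FPKM for one gene of the given category, plus its group.

    The planted inequalities hold with factor ``margin`` (not just
    ``fold``) before noise and leakage are applied.
    """
    n = len(tissues)
    t_idx = tissues.index(config.target_tissue)
    other_idx = [i for i in range(n) if i != t_idx]
    cutoff, m = config.detection_cutoff, config.margin
    row = np.empty(n)
    group: tuple[str, ...] = ()

    if category == "not_detected":
        row[other_idx] = _baseline(rng, config, n - 1)
        row[t_idx] = rng.uniform(0, cutoff)
    elif category == "tissue_enriched":
        others = _baseline(rng, config, n - 1)
        row[other_idx] = others
        row[t_idx] = max(m * others.max() * rng.uniform(1.0, 2.0), m * cutoff)
    elif category == "group_enriched":
        k = int(rng.integers(config.group_min, config.group_max + 1))
        members = [t_idx] + list(rng.choice(other_idx, size=k - 1,
                                            replace=False))
        outside = [i for i in range(n) if i not in members]
        out_vals = _baseline(rng, config, len(outside))
        row[outside] = out_vals
        level = max(m * out_vals.max() * rng.uniform(1.0, 1.5), 2 * cutoff)
        row[members] = level * rng.uniform(1.0, 2.0, size=k)
        group = tuple(sorted(tissues[i] for i in members))
    elif category == "tissue_enhanced":
        # target sits margin-fold above the panel mean but below fold x a
        # crowd of companion tissues, and the crowd is larger than any
        # allowed group so no group rule can fire
        n_comp = min(config.group_max + 3, n - 2)
        base = max(float(_baseline(rng, config, 1)[0]), 2 * cutoff)
        comp = list(rng.choice(other_idx, size=n_comp, replace=False))
        rest = [i for i in other_idx if i not in comp]
        row[comp] = base * rng.uniform(0.8, 1.25, size=n_comp)
        row[rest] = base * rng.uniform(0.005, 0.05, size=len(rest))
        s_others = row[other_idx].sum()
        row[t_idx] = 1.02 * m * s_others / (n - m)
    elif category == "expressed_in_all":
        level = max(float(_baseline(rng, config, 1)[0]), 4 * cutoff)
        row[:] = level * rng.uniform(0.7, 1.4, size=n)
    elif category == "mixed":
        # detected in a crowd bigger than group_max but not everywhere,
        # all at comparable levels so no fold rule fires
        hi = min(config.group_max + 8, n - 2)
        n_det = int(rng.integers(config.group_max + 2, hi + 1))
        level = max(float(_baseline(rng, config, 1)[0]), 3 * cutoff)
        det = list(rng.choice(other_idx, size=n_det, replace=False))
        rest = [i for i in other_idx if i not in det]
        row[det] = level * rng.uniform(0.9, 1.3, size=n_det)
        row[rest] = rng.uniform(0, 0.5 * cutoff, size=len(rest))
        row[t_idx] = level * rng.uniform(0.9, 1.3)
    else:
        raise ValueError(f"unknown category {category!r}")
    return row, group


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (matrix, annotation, truth) for a synthetic panel.

    Deterministic given ``config.seed``. The truth table records each
    gene's planted category, its planted group (for group-enriched genes)
    and the planted fold margin.
    """
    rng = np.random.default_rng(config.seed)
    tissues = config.tissues

    gene_rows, truth_rows, gene_ids = [], [], []
    i = 0
    for category in CATEGORIES:
        for _ in range(config.counts.get(category, 0)):
            row, group = _plant_row(rng, config, category, tissues)
            gene_rows.append(row)
            truth_rows.append({"category": category, "group": group,
                               "planted_fold": config.margin})
            gene_ids.append(f"G{i:05d}")
            i += 1
    order = rng.permutation(len(gene_ids))
    values = np.asarray(gene_rows)[order]
    gene_ids = [gene_ids[j] for j in order]
    truth = pd.DataFrame([truth_rows[j] for j in order], index=gene_ids)
    truth.index.name = "gene"

    # expand tissues into replicate samples
    sample_ids, sample_tissue, tissue_values = [], [], []
    lo, hi = config.replicate_range
    for tissue in tissues:
        n_rep = (config.target_replicates if tissue == config.target_tissue
                 else int(rng.integers(lo, hi + 1)))
        for r in range(n_rep):
            sample_ids.append(f"{tissue.replace(' ', '_')}_{r + 1}")
            sample_tissue.append(tissue)
            tissue_values.append(tissues.index(tissue))
    profile_cols = values[:, tissue_values]

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + config.noise_cv ** 2))
        noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                  size=profile_cols.shape))
        profile_cols = profile_cols * noise

    matrix = pd.DataFrame(profile_cols, index=gene_ids, columns=sample_ids)
    annotation = pd.DataFrame(
        {
            "tissue": sample_tissue,
            "donor": [f"donor_{k:03d}" for k in range(len(sample_ids))],
            "compartment": "whole",
            "lane": [f"lane_{k // config.lane_size + 1}"
                     for k in range(len(sample_ids))],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if config.leakage_rate > 0:
        matrix = apply_barcode_leakage(matrix, annotation, config.leakage_rate)
    return validate_matrix(matrix), validate_annotation(annotation), truth


def apply_barcode_leakage(
    matrix: pd.DataFrame, annotation: pd.DataFrame, r: float
) -> pd.DataFrame:
    """Mix a fraction ``r`` of each sample's signal into its lanemates.

    Per gene and lane, each of the n samples keeps (1 - r) of its signal
    and receives r / (n - 1) of each lanemate's; single-sample lanes are
    unchanged. The per-gene lane total is conserved exactly, making the
    operator linear and order-independent.
    """
    if not 0 <= r < 1:
        raise ValueError("leakage rate must be in [0, 1)")
    validate_annotation(annotation, matrix)
    lanes = annotation.loc[matrix.columns, "lane"]
    if (lanes.astype(str).str.len() == 0).any():
        missing = lanes.index[lanes.astype(str).str.len() == 0][0]
        raise ValueError(f"sample {missing!r} has no lane assignment")
    out = matrix.copy()
    for _, samples in lanes.groupby(lanes):
        cols = list(samples.index)
        n = len(cols)
        if n < 2:
            continue
        block = matrix[cols].to_numpy(dtype=float)
        lane_total = block.sum(axis=1, keepdims=True)
        out[cols] = (1 - r) * block + (r / (n - 1)) * (lane_total - block)
    return out


@dataclass
class RecoveryReport:
    """Agreement between planted and predicted categories."""

    confusion: pd.DataFrame  # planted (rows) x predicted (columns)
    accuracy: float
    per_category: dict[str, float]


def recovery_report(
    truth: pd.DataFrame, predicted: pd.DataFrame
) -> RecoveryReport:
    """Score predicted categories against the planted truth."""
    diff = truth.index.symmetric_difference(predicted.index)
    if len(diff) > 0:
        raise ValueError(f"gene sets differ by {len(diff)} genes")
    planted = truth["category"].astype(str)
    called = predicted.loc[truth.index, "category"].astype(str)
    confusion = pd.crosstab(planted, called).reindex(
        index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    confusion.index.name = "planted"
    confusion.columns.name = "predicted"
    accuracy = float((planted == called).mean())
    per_category = {}
    for c in CATEGORIES:
        mask = planted == c
        per_category[c] = (float((called[mask] == c).mean())
                           if mask.any() else float("nan"))
    return RecoveryReport(confusion, accuracy, per_category)


def elevated_retention(truth: pd.DataFrame, predicted: pd.DataFrame) -> float:
    """Fraction of genes planted in an elevated category that are still
    called elevated (any of the three elevated categories)."""
    planted_elev = truth.index[truth["category"].isin(ELEVATED)]
    if len(planted_elev) == 0:
        return float("nan")
    called = predicted.loc[planted_elev, "category"]
    return float(called.isin(ELEVATED).mean())
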