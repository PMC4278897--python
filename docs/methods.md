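# Methods

## Data model and formats

The pipeline starts from quantified expression: a genes × samples matrix
of FPKM values (TSV, UTF-8, first column gene ids, header row sample ids,
`.` decimal separator) and a sample annotation TSV with columns
`sample_id`, `tissue`, `donor`, `compartment` (`whole`, `islet` or
`exocrine`) and `lane` (may be empty). No read-level processing, alignment
or re-quantification is performed or supported. Matrices must be complete:
a missing measurement has to be encoded upstream as 0 or the sample
dropped. Gene identifiers are opaque strings; no genomic coordinates are
handled.

Replicates are averaged per tissue with the unweighted arithmetic mean on
the linear FPKM scale (not log scale) — the natural reading of "average
FPKM". Where a log scale is wanted (plots, transforms), `log2_pseudo`
applies log2(FPKM + 1), the +1 pseudo-count keeping zeros at zero. All
annotated samples of a compartment contribute to the average; no QC-based
sample exclusion is built in.

## Classification

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `detection_cutoff` | 1 FPKM | detection limit, ≈ one mRNA per cell |
| `fold` | 5 | enrichment fold threshold |
| `group_min`, `group_max` | 2, 7 | allowed group-enriched set sizes |

Fold comparisons are inclusive (≥), and detection is FPKM ≥ cutoff: the
inequalities must be determinate at the boundary, and "5-fold higher" is
read as "at least 5-fold". Categories are tested in the order
not detected → tissue enriched → group enriched → tissue enhanced →
expressed in all → mixed. Placing the three elevated categories ahead of
"expressed in all" is a deliberate design choice: an enhanced gene that
happens to be detected in every tissue must still count as elevated,
otherwise the elevated = enriched + group + enhanced accounting could not
hold. The tissue-enhanced comparison uses the mean over **all** tissues,
target included. The score `x_t / max_{i≠t} x_i` is computed for every
gene regardless of category; reporting layers may blank it for
non-elevated genes.

### Group search

A qualifying group must satisfy `min_G ≥ fold · max_outside`. Because
`fold > 1`, every tissue expressed at or above the group minimum must
itself belong to the group (an equal value outside would force
`min_G ≥ fold · min_G`, impossible for positive values), so qualifying
groups are exactly prefixes of the FPKM-descending tissue order. The
implementation therefore scans prefixes of size `group_min..group_max`
containing the target and returns the smallest qualifying one; FPKM ties
are broken by tissue label so output is deterministic. If a prefix covers
the whole panel (only possible when the panel has ≤ `group_max` tissues)
the outside maximum is taken as 0 and the condition holds trivially. The
scan is tested against exhaustive subset enumeration on random panels,
zeros and ties included.

## Composition, similarity

Pool fractions use the summed FPKM of **all** genes in the denominator,
including not-detected genes (each contributes < cutoff, so the difference
from an expressed-only denominator is negligible, but the convention is
fixed). The expressed fraction's denominator is likewise all genes of the
input matrix. The dynamic range is (min detected FPKM, max FPKM, ratio)
within the target column.

Sample similarity uses Spearman rank correlation with average ranks for
ties (scipy's convention). Two gene-selection modes exist because both
appear in practice: the full gene set (default), and per pair the genes
detected in at least one of the two samples. Rank correlation is invariant
under monotone transforms, so log-transforming first changes nothing — a
property the tests exercise. Pairs with a constant column get NaN.

## Compartment enrichment

Isolate preparations (replicate-averaged like tissues) are appended to the
comparison panel one at a time as the classification target. By default
the parent tissue is **excluded** from the comparison
(`exclude_parent=True`): a gene expressed at, say, 60 in the islet isolate
and 40 in whole pancreas against a background of 10 is biologically
islet-elevated, but the whole-pancreas value — itself largely made of the
isolate's signal — would block the call. Both behaviours are available
since the right choice depends on how independent the parent measurement
is. Elevated sets of the two isolates and the whole tissue are partitioned
into the seven exclusive Venn regions; `isolate_only` is
(islet ∪ exocrine) \ whole.

## Sharing network

Group-enriched genes are tallied by their exact tissue set; each distinct
combination becomes a node sized by the square root of its gene count
(the usual bubble-area convention), linked to its member tissues.
Tissue-enriched genes are included as the singleton combination of the
target (toggleable). Per-tissue sharing tallies count genes, not
combinations. Output is plain node/edge TSV; layout and rendering are left
to graph viewers.

## Synthetic panels

The generator emulates the structure of a multi-tissue bulk RNA-seq FPKM
panel: 27 tissues, 1–4 replicate samples each (the target tissue gets 2),
baseline expression drawn log-normally (ln-scale location 0.5, scale 2.0,
giving a panel-wide dynamic range of roughly 10^4–10^5), and per-category
planted genes whose defining inequality holds with a safety margin
(default 8×, stricter than the 5× classification fold) before noise.
Defaults plant 2,000 genes: 600 not detected, 100 each
enriched/group/enhanced, 700 expressed-in-all, 400 mixed — ubiquitous and
silent genes dominating, elevated genes a small minority, as in real
panels. Construction notes:

- *not detected*: target drawn uniformly in [0, cutoff); other tissues
  free. Genes landing just under the cutoff can cross it under replicate
  noise — the one realistic confusion mode (not_detected → mixed).
- *enriched*: target set to margin × the others' maximum (at least
  margin × cutoff).
- *group enriched*: a random group of 2–7 tissues placed at a common level
  ≥ margin × the outside maximum, members within 2× of each other so no
  sub-group or singleton rule can fire; the planted set is provably the
  minimal qualifying group, so recovery can compare groups exactly.
- *enhanced*: the target is placed at 1.02 × margin × mean against a crowd
  of `group_max + 3` companion tissues at a common level — large enough
  that no 2–7 group exists and the companion maximum blocks enrichment.
- *expressed in all*: a common level ≥ 4 × cutoff, jittered within ±40%.
- *mixed*: detected in a crowd of `group_max + 2 .. group_max + 8` tissues
  at levels within 0.9–1.3× of each other (so neither the group nor the
  enhanced rule can fire), silent elsewhere.

Replicate noise is multiplicative log-normal with unit mean and
coefficient of variation `noise_cv` (default 0.05). Barcode leakage models
index misassignment between samples multiplexed on a sequencing lane: on
the FPKM scale, each sample keeps (1 − r) of its signal and receives
r/(n−1) of each lanemate's (default r = 0.001, lanes of 8). This is a
desk-scale surrogate for read-level misassignment; it is exactly linear
and conserves per-gene lane totals, both asserted in tests. A single
seeded RNG stream drives everything, so outputs are bit-reproducible.

What the simulator does **not** emulate: gene–gene correlation, donor
effects, library-size or gene-length bias, count noise at low expression,
or compositional coupling between genes. Passing recovery tests therefore
demonstrates the correctness of the decision rules and their robustness to
calibrated noise/leakage — not classifier performance on real tissue
panels, where margins are not guaranteed.

## Problem sizes and numerics

The test suite and acceptance script run on 2,000-gene × 27-tissue panels
(about 70 samples), classification taking well under a second, and on 500
random 10-tissue rows for the group-search/enumeration cross-check —
sizes chosen so the whole suite completes in seconds while still
exercising every rule, tie and zero case. Composition fractions are exact
ratios (conservation holds to 1e-12); leakage conservation holds to
rounding (~1e-16 relative). Degenerate inputs are defined explicitly:
score is `inf` for genes expressed only in the target and NaN for silent
genes; Spearman pairs with a constant column are NaN; dynamic range is an
error when nothing is detected.

## Known limitations

- The scheme is deterministic thresholding; there is no statistical test,
  FDR, or uncertainty on category calls.
- Only one target tissue per run; multi-target analyses are re-runs.
- Isolate enrichment depends on the `exclude_parent` interpretation
  discussed above; with few isolate replicates the calls are sensitive to
  single-donor effects the simulator does not model.
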