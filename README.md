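# tissuespec

Tissue-specificity analysis of bulk RNA-seq FPKM panels.

Given a gene × sample FPKM matrix covering a panel of tissues (with
replicate samples per tissue), `tissuespec` answers the question a
tissue-transcriptome study asks of every gene: *is this gene's expression
specific to one tissue, shared by a small group of tissues, broadly
elevated, ubiquitous, or absent?* It is aimed at anyone profiling an organ
(the defaults are tuned to a pancreas-style analysis across 27 human
tissues) who wants the standard specificity categories, the mRNA-pool
decomposition, sample-similarity QC, isolate/compartment enrichment, and
the tissue-sharing network — reproducibly, from a single matrix and
annotation table.

## The classification scheme

Replicate samples are averaged per tissue on the linear FPKM scale to give
a profile `x_g = (x_g,1, …, x_g,N)` for each gene *g* over *N* tissues.
With a detection cutoff *c* = 1 FPKM (roughly one mRNA per cell), a fold
threshold *f* = 5, and a target tissue *t*, each gene receives exactly one
of six categories, tested in this order:

1. **not detected** — `x_t < c`;
2. **tissue enriched** — `x_t ≥ f · max_{i≠t} x_i`;
3. **group enriched** — some group *G* of 2–7 tissues with `t ∈ G` has
   `min_{i∈G} x_i ≥ f · max_{i∉G} x_i`;
4. **tissue enhanced** — `x_t ≥ f · mean(x)` over all *N* tissues;
5. **expressed in all** — `x_i ≥ c` for every tissue;
6. **mixed** — detected in the target but none of the above.

Categories 2–4 together are the **elevated** genes. Every gene also gets a
tissue-specific score `x_t / max_{i≠t} x_i` (`inf` if expressed nowhere
else). The group search sorts tissues by FPKM descending and scans
prefixes, which is provably equivalent to exhaustive subset enumeration
(and tested against it).

On top of the classifier the package computes: the fraction of the
tissue's summed FPKM (its mRNA pool) carried by each category; the
expressed-gene fraction and dynamic range; pairwise Spearman correlations
between samples; elevated genes of isolate preparations (e.g. purified
islet and exocrine fractions) versus the whole-tissue panel, with a
three-set Venn partition; and the node/edge tables of the network linking
group-enriched gene combinations to their member tissues.

A bundled simulator generates panels with genes *planted* in each category
(with configurable safety margins), multiplicative replicate noise, and
in-lane barcode leakage (~0.1% index misassignment between multiplexed
samples), together with ground-truth labels — so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
import tissuespec as ts

cfg = ts.SimulationConfig(seed=42)          # 27 tissues, 2000 genes,
matrix, annotation, truth = ts.simulate_dataset(cfg)  # 5% CV, 0.1% leakage
profile = ts.average_replicates(matrix, annotation)
classes = ts.classify_all(profile, cfg.params())
print(ts.category_census(classes))
summary = ts.mrna_pool_fractions(profile, classes, "pancreas")
print(f"elevated fraction of pool {summary.elevated_fraction:.3f}")
print("recovery accuracy %.4f" % ts.recovery_report(truth, classes).accuracy)
```

prints

```
{'not_detected': 588, 'tissue_enriched': 100, 'group_enriched': 100,
 'tissue_enhanced': 100, 'expressed_in_all': 700, 'mixed': 412,
 'elevated': 300}
elevated fraction of pool 0.944
recovery accuracy 0.9940
```

All 300 planted elevated genes are recovered (the ~0.6% misses are
not-detected genes planted just under the 1 FPKM cutoff that replicate
noise nudged across it, called mixed instead). The elevated genes — 15% of
the panel — carry 94% of the simulated tissue's mRNA pool, the hallmark of
a secretory organ dominated by a few highly expressed transcripts.

The same analyses are available from the shell:

```sh
tissuespec simulate --seed 42 -o sim/
tissuespec validate sim/matrix.tsv sim/annotation.tsv
tissuespec classify sim/matrix.tsv sim/annotation.tsv \
    --target pancreas -o classes.tsv
tissuespec compose classes.tsv sim/matrix.tsv sim/annotation.tsv \
    --target pancreas -o composition.tsv
tissuespec run --config run.yaml      # full pipeline + manifest
```

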