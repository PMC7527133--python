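# cohortnet

Consensus co-occurrence network inference for bacterioplankton OTU tables.

Freshwater lakes are dominated year-round by a handful of streamlined
bacterial genera, and a central question is whether that dominance is
driven by the physical environment or by interactions within the
microbial community. One way to probe this is to infer a co-occurrence
network from long-term 16S amplicon time series and from
dilution-to-few-cells mixed cultures, and then study the *primary (1°)
cohort* of a target taxon — the first neighbors of its OTUs in the
network — across the two datasets. Because single correlation estimators
on compositional count data are unreliable, edges are accepted only by
consensus of several methods.

`cohortnet` implements that analysis end to end for anyone working with
OTU count tables (samples × OTUs, 7-rank taxonomy, per-sample metadata):

* **normalization & filtering** — exact rarefaction to an even depth
  (1,500 reads/sample for time series, 500 for cultures), singleton
  removal, and a filter-parameter sweep scored by sparsity ≤ 50% and mean
  inverse-Simpson n_eff ≥ 10;
* **four association estimators** — Pearson (BH-adjusted), SparCC basis
  correlations ρᵢⱼ = (ωᵢ + ωⱼ − tᵢⱼ)/(2√(ωᵢωⱼ)) estimated from log-ratio
  variances with pair exclusion and bootstrap pseudo *P* values,
  Dice–Sørensen on presence/absence, and CLR + L1-penalized neighborhood
  selection ("mb") with StARS stability selection of the penalty;
* **consensus networks** — edges kept at |coef| > 0.3 (or any mb
  detection) when supported by ≥ 2 methods, weighted by the mean
  correlation;
* **network statistics** — Newman's nominal assortativity per taxonomic
  rank, modularity Q, 1°-cohort extraction and cohort overlap;
* **statistical screens** — environmental collinearity pruning
  (missingness/VIF/|r|), Pearson screens at α = 0.001 with BH,
  Kruskal–Wallis by lake-cycle phase with critical-difference post hoc,
  phylogenetic-distance-vs-correlation, and cross-dataset
  abundance/prevalence comparisons;
* **a seeded synthetic-community generator** — taxonomy + ultrametric
  tree, planted signed interactions, seasonal time-series counts, a
  dilution mixed-culture simulator (98 cultures, ~10 founder cells,
  detection censoring to ~60 usable cultures), and environmental
  covariates — so the whole pipeline is testable against known ground
  truth.

See `docs/methods.md` for models, parameters and design decisions.

## Worked example

Run the default benchmark: a synthetic 100-OTU community observed in 200
weekly samples at depth 1,500, with 30 planted signed interactions at
strength 0.8, analyzed by the time-series trio (pearson + sparcc + mb):

```python
from cohortnet import PipelineConfig, run_pipeline

net, reports = run_pipeline(PipelineConfig(seed=1))
rec = reports["recovery"]
print(f"consensus: {net.n_edges} edges among {net.graph.number_of_nodes()} nodes")
print(f"recovery vs planted truth: precision={rec.precision:.3f} "
      f"recall={rec.recall:.3f} sign_accuracy={rec.sign_accuracy:.3f}")
print(net.to_edge_df().head(4).to_string(index=False))
```

prints

```
consensus: 23 edges among 100 nodes
recovery vs planted truth: precision=0.870 recall=0.667 sign_accuracy=1.000
  otu_i   otu_j    weight  sign        supporters  n_methods  sign_conflict
otu0005 otu0054  0.508816     1 mb,pearson,sparcc          3          False
otu0006 otu0019  0.487006     1 mb,pearson,sparcc          3          False
otu0007 otu0024 -0.314258    -1         mb,sparcc          2          False
otu0012 otu0027  0.412785     1 mb,pearson,sparcc          3          False
```

So 20 of the 23 consensus edges are planted interactions (precision
0.870), two thirds of the planted network is recovered at this strength
and sample size, and every recovered edge has the correct sign. Over
seeds 1–5 the median precision is 0.87 and median recall 0.77. Cohorts
are then extracted with `first_neighbors(net, target_otus)` and compared
with `cohort_overlap`.

The same pipeline runs from the shell:

```sh
cohortnet simulate --n-otus 100 --n-samples 200 --seed 1 --out-dir data/
cohortnet run --dataset TS --seed 1 --out-dir results/
```

writing the consensus edge list (TSV), GraphML, per-method edge tables
and the full parameter log.

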