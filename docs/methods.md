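# Methods

`cohortnet` re-implements, as a tested library, the consensus co-occurrence
network analysis used to identify the "primary cohorts" (first-neighbor
sets) of dominant freshwater bacterioplankton from 16S amplicon OTU tables,
together with a synthetic-community generator that supplies ground-truthed
inputs for every stage. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## The analysis pipeline

**Normalization.** Count tables are rarefied to an even depth by exact
multivariate hypergeometric subsampling (without replacement): 1,500 reads
per sample for the lake time series (TS), 500 per culture for the dilution
mixed cultures (MC). Samples below the target depth are dropped, not
up-sampled. Rarefaction makes the data strictly compositional: only
relative information survives, which is why a compositionally aware
estimator (SparCC) and a log-ratio graph model sit alongside plain Pearson.

**Rare-OTU filtering.** Rare OTUs inflate false co-occurrence signal, so
the TS table is filtered by a grid sweep over (minimum detection frequency,
minimum total relative abundance). Every grid point is scored against two
network-readiness recommendations — table sparsity ≤ 50% and mean inverse
Simpson diversity n_eff = 1/Σp² ≥ 10 — and among qualifying points the one
retaining the most OTUs wins (ties: lower detection threshold, then lower
abundance threshold). The TS preset (`ts_filter_preset`) is detection in
≥ 29 samples and mean relative abundance ≥ 0.1%. "Total relative
abundance" defaults to summed per-sample proportions with a mean-proportion
mode selectable; both comparisons default to inclusive (≥) with a strict
flag. The MC table instead only has singletons (total count ≤ 1) removed.

**Association estimators.** Four estimators run on the filtered table:

* *Pearson* on relative abundances, two-sided t-test p-values,
  Benjamini–Hochberg step-up adjustment over the upper triangle
  (Benjamini–Yekutieli selectable). Zero-variance OTUs are NaN and excluded
  from the test count.
* *SparCC.* Fractions are drawn from Dirichlet(counts + 1) per sample;
  the log-ratio variance matrix t_ij = Var log(x_i/x_j) is averaged over
  `max_iter` = 100 draws. Under the sparse-network approximation
  t_ij ≈ ω_i + ω_j the basis variances solve the linear system
  `(diag(d) + A) ω = rowsum(T)` over included pairs, and basis correlations
  follow as ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_i ω_j)), clipped to [−1, 1].
  Up to `exiter` = 10 exclusion rounds remove the single most correlated
  pair while max |ρ| > `th` = 0.1 and re-solve; negative solved variances
  are floored at 1e−10 and flagged. `max_iter` is read as the number of
  Dirichlet draws whose variation matrices are averaged — the reproducible
  reading of the original algorithm. Bootstrap pseudo p-values (100
  bootstraps, two-sided) resample each OTU's counts independently across
  samples, which destroys cross-OTU association while preserving marginals;
  p = (1 + #{|ρ_boot| ≥ |ρ_obs|}) / (n_boot + 1), so the smallest attainable
  value is 1/101.
* *Dice–Sørensen* on the binarized table: 2|a∩b|/(|a|+|b|); pairs involving
  an everywhere-absent OTU are undefined.
* *Neighborhood selection ("mb") with StARS.* Counts are CLR-transformed
  (log(count + 1) minus the sample mean log; pseudocount 1 because inputs
  are counts — multiplicative zero replacement is a documented alternative
  not implemented here). Each OTU is lasso-regressed on all others over a
  geometric path of `nlambda` = 20 penalties from λ_max (first empty
  graph) down by `lambda_min_ratio` = 1e−2. StARS draws 50 subsamples of
  size min(⌊10√n⌋, ⌊0.8 n⌋) without replacement, measures mean edge
  instability 2θ(1−θ) per penalty from subsample edge frequencies θ, and
  selects the densest penalty whose running-supremum instability stays
  ≤ β = 0.05 (the method's canonical default). The final graph refits on
  the full data at the selected penalty; neighborhoods are OR-combined
  (AND selectable) and each edge's sign is the sign of the mean of its two
  regression coefficients.

**Consensus.** Per-method edges are retained when |coef| > 0.3 (strict, per
the retention rule; inclusive selectable) — except the mb graph, whose
detections are retained unconditionally. An edge enters the consensus
network when ≥ 2 methods support it. Edge weight is the mean of the
coefficient-bearing supporters; mb votes but contributes no coefficient
(its output is not a correlation). Supporter sign disagreements are kept
and flagged (`sign_conflict`) rather than dropped. No p-value cutoff is
applied before the coefficient threshold by default (an optional
`max_p_adj` exists), matching the coefficient-only retention rule. The TS
method trio is {pearson, sparcc, mb}; MC is {pearson, dice, mb}. The node
set is the full filtered OTU universe, so isolated OTUs remain queryable.

**Network statistics.** Nominal (categorical) assortativity per taxonomic
rank uses Newman's mixing-matrix coefficient r = (Σe_ii − Σa_i b_i)/(1 −
Σa_i b_i), each undirected edge counted once in each direction; a
single-label network returns NaN. Modularity uses greedy agglomerative
community search with Q = Σ_c (e_cc − a_c²). Both ignore edge signs and
weights — the statistics are topological; sign-aware variants are out of
scope. Primary cohorts are first neighbors of a user-supplied target OTU
set (manual subgroup splits, e.g. basal vs core members of a genus, are
expressed as explicit id lists), each neighbor annotated by its
strongest-|weight| edge to the target; cohort overlap reports directional
shared fractions |A∩B|/|A| and per-neighbor sign agreement.

**Statistical screens.** Environmental parameters are pruned in two
stages: missingness > 40%, then iterative removal (most-missing first,
ties by highest VIF) while any VIF = 1/(1−R²) > 10 or pairwise |r| > 0.7.
The clade × parameter screen uses pairwise-complete Pearson with BH over
all tests and flags |r| > 0.3 with adjusted p < 0.001 (the display filter
applied after adjustment). Seasonal differences use Kruskal–Wallis per
clade over the six phase labels, with a post hoc all-pairs mean-rank-sum
comparison against the normal-approximation critical difference
z_{1−α/k(k−1)} √(N(N+1)/12 (1/n_i + 1/n_j)); a phase "stands out" when it
differs from at least two others. Phylogenetic distance vs co-occurrence
correlates patristic distance with consensus edge weight over
network-connected (target, neighbor) pairs only (treating unconnected pairs
as zero is available behind a flag-level variant but is not the default
reading of an "averaged edge value from the network"). Cross-dataset
comparisons correlate log10 av.ra (zeros excluded) and prevalence over
shared OTUs, overall and per designated subset, BH-adjusted together.

## The synthetic community

The generator supplies every input the pipeline consumes, with known
ground truth:

* **Taxonomy**: a random nested 7-rank hierarchy (domain fixed at
  Bacteria; species labels unique per OTU) backed by an ultrametric tree
  with fixed per-rank node heights, so OTUs sharing any rank label are
  monophyletic and patristic distance is determined by the deepest shared
  rank. Branching at each rank is 1 + Poisson(0.7) children per group.
* **Planted interactions**: `n_edges` unordered pairs sampled without
  replacement; with `assortative_bias` b > 0 within-phylum pairs get
  sampling weight e^b, emulating taxonomic assortativity. Each edge is
  negative with probability `frac_negative` (default 0.25) and carries a
  common `strength` in (0, 1].
* **Time series**: latent log-abundance = baseline N(0, 1.2) + seasonal
  sinusoid (amplitude U(0, 0.6); phase shared per phylum ± 0.5 rad,
  giving clade-structured dynamics) + per-edge shared Gaussian factor
  scaled by 1.5 × strength (anti-phase for negative edges) + N(0, 0.5)
  noise; counts are multinomial(softmax) at depth 1,500 over weekly dates.
  Phase labels follow the month (spring/autumn/winter; summer samples
  cycle through epilimnion/metalimnion/hypolimnion). The latent-factor
  coupling was chosen over Lotka–Volterra dynamics because it gives
  directly controllable pairwise correlation strength — which is exactly
  what the estimators are evaluated against. A consequence worth knowing:
  two planted edges sharing an endpoint create *conditional* dependence
  between the far ends (zero marginal covariance does not mean zero
  partial correlation), so the neighborhood-selection graph legitimately
  links them; conditional-independence recovery is therefore tested on
  explicitly Markov-structured data.
* **Dilution cultures**: 98 one-ml cultures, founders ~ Poisson(10)
  assigned by a lake composition vector. A random subset of taxa is
  culturable in the medium, chosen greedily so that the culturable taxa
  hold ≈ 9.5% of the inoculum *mass* (most freshwater taxa do not grow in
  filtered-lake-water media, and the censoring yield depends on the
  culturable share of cells, not of taxa — fixing the mass fraction keeps
  the yield stable across community realizations, which a per-taxon
  culturability coin-flip does not). Culturable founded OTUs grow by 1e4
  with lognormal(0, 0.5) noise; others stay at founder level. The optional
  dependency rule (default off) marks designated positive edges obligate:
  an OTU grows only if all obligate partners were founded. A culture is
  detected when total grown biomass reaches 0.5 of one fully-grown
  founder's yield, giving detection probability ≈ 1 − e^(−10·0.095)
  deflated slightly by growth noise ≈ 0.6, i.e. ≈ 60 of 98 cultures,
  mirroring the experimental yield. Reads are multinomial over biomass at
  depth 500. The inoculum composition is an explicit parameter — the lake
  table is not assumed to apply directly.
* **Environment**: each parameter is a standardized seasonal sinusoid +
  AR(1)(0.7) series; linked parameters are built by orthogonalized mixing
  to hit the target Pearson correlation with an OTU's relative-abundance
  series exactly in-sample; missing entries are inserted independently at
  the requested rate. Default 14 parameters.

All generators are deterministic under a fixed seed; derived seeds in the
pipeline come from one `numpy` generator seeded by the config.

## What the benchmarks show (and what they do not)

The recovery benchmark (100 OTUs, 200 samples at depth 1,500, 30 planted
edges at strength 0.8, consensus of pearson+sparcc+mb at |coef| > 0.3 and
≥ 2 methods, seeds 1–5) establishes that the implementation recovers
strong pairwise associations with median precision ≥ 0.8 and recall
≥ 0.7, and the edge-free null keeps consensus edge density below 1%.
These are correctness checks of the estimators and the consensus logic,
not ecological validation: the generator plants stationary pairwise
latent-factor couplings, whereas real interactions are dynamic,
higher-order, and confounded with shared environmental drivers; the
taxonomy is a caricature of SILVA; and the culture model reduces growth to
a culturability coin-flip plus an optional obligate-partner rule. Passing
here means the statistics do what they claim on data satisfying their
assumptions, not that a real lake network is correct.

Known numerical/behavioral notes:

* SparCC's bootstrap pseudo p-values are approximately, not exactly,
  uniform under independence: within-column resampling breaks the constant
  row-sum, and communities with a strongly dominant OTU acquire mild
  conservativeness. Calibration is checked by KS on 100 pairs from a
  30-OTU even-seasonality-free community.
* Nominal assortativity under random relabeling has the usual small
  negative finite-size bias (order 1/m); the permutation-null test checks
  centering relative to the null spread, and the implementation is
  cross-checked exactly against networkx.
* Greedy modularity is a heuristic; it is validated against exhaustive
  partition search on graphs of ≤ 8 nodes and against hand-computed Q for
  canonical graphs (two bridged triangles: Q = 6/7 − 1/2).
* Ties in the SparCC exclusion loop (two pairs at identical |ρ|) resolve
  by first array index — deterministic but arbitrary.
* The problem sizes used by the test-suite and the acceptance script (50
  OTU nulls, 30-OTU calibration tables, 12-taxon occupancy checks, 5
  benchmark seeds) were chosen to make the whole suite a few minutes of
  single-core compute while keeping Monte-Carlo error well inside the
  asserted tolerances.

## Scope

Sequence-level processing (read joining, chimera removal, OTU picking,
taxonomy assignment), metagenome assembly/binning, pathway cataloguing,
and network drawing/layout are out of scope; inputs are OTU count tables
with taxonomy, and outputs are edge lists, GraphML, and TSV reports.
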