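"""Edge thresholding, multi-method consensus, recovery scoring, and the
end-to-end pipeline.

An OTU pair enters a method's edge set when its coefficient exceeds 0.3 in
absolute value (Pearson, SparCC, Dice-Sorensen) or when the neighborhood-
selection graph detects it at all.  The consensus network keeps pairs
supported by at least two methods; its edge weight is the mean of the
available correlation coefficients (the mb graph votes but contributes no
coefficient), and sign disagreements between supporters are retained and
flagged rather than dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import synthetic
from .correlations import (CorrelationResult, dice_sorensen, mb_network,
                           pearson_matrix, sparcc, sparcc_with_pvalues)
from .otu_table import (InvalidArgumentError, OtuTable, RANKS, drop_singletons,
                        filter_sweep, apply_filter, rarefy, summarize,
                        ts_filter_preset)

logger = logging.getLogger("cohortnet")


@dataclass
class EdgeSet:
    """One method's thresholded edges: sorted OTU pair -> (sign, coef)."""

    method: str
    edges: dict
    universe: frozenset

    def pairs(self) -> set:
        return set(self.edges)


def threshold_edges(result: CorrelationResult, min_abs_coef: float = 0.3,
                    inclusive: bool = False,
                    max_p_adj: float | None = None) -> EdgeSet:
    """Apply the retention rule to one method's matrices.

    Coefficient methods keep pairs with ``|coef| > min_abs_coef`` (``>=``
    with ``inclusive=True``), optionally also requiring ``p_adj <=
    max_p_adj``; the mb method keeps its support adjacency unconditionally
    with its regression-derived signs.  Dice edges are always positive.
    """
    if not 0.0 <= min_abs_coef <= 1.0:
        raise InvalidArgumentError("min_abs_coef must be in [0, 1]")
    ids = result.otus
    edges: dict = {}
    if result.method == "mb":
        sup = result.support.to_numpy()
        sgn = result.sign.to_numpy()
        iu, ju = np.triu_indices(len(ids), k=1)
        for a, b in zip(iu, ju):
            if sup[a, b]:
                s = int(sgn[a, b]) or 1
                edges[(ids[a], ids[b])] = (s, None)
    else:
        coef = result.coef.to_numpy()
        padj = result.p_adj.to_numpy() if result.p_adj is not None else None
        iu, ju = np.triu_indices(len(ids), k=1)
        for a, b in zip(iu, ju):
            c = coef[a, b]
            if np.isnan(c):
                continue
            keep = abs(c) >= min_abs_coef if inclusive else abs(c) > min_abs_coef
            if keep and max_p_adj is not None and padj is not None:
                keep = not np.isnan(padj[a, b]) and padj[a, b] <= max_p_adj
            if keep:
                sign = 1 if result.method == "dice" else (1 if c >= 0 else -1)
                edges[(ids[a], ids[b])] = (sign, float(c))
    return EdgeSet(result.method, edges, frozenset(ids))


@dataclass
class ConsensusNetwork:
    """Nodes (all filtered OTUs) and >=2-method consensus edges."""

    graph: nx.Graph
    min_methods: int = 2

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def edge_density(self) -> float:
        n = self.graph.number_of_nodes()
        possible = n * (n - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def to_edge_df(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(dict(otu_i=a, otu_j=b, weight=d["weight"],
                             sign=d["sign"], supporters=",".join(d["methods"]),
                             n_methods=len(d["methods"]),
                             sign_conflict=d["sign_conflict"]))
        df = pd.DataFrame(rows, columns=["otu_i", "otu_j", "weight", "sign",
                                         "supporters", "n_methods",
                                         "sign_conflict"])
        return df.sort_values(["otu_i", "otu_j"]).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        df = self.to_edge_df()
        df["weight"] = df["weight"].map(lambda w: f"{w:.10g}")
        df.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            d["methods"] = ",".join(d.pop("methods"))
            if d["weight"] is None or (isinstance(d["weight"], float)
                                       and np.isnan(d["weight"])):
                d["weight"] = 0.0
        nx.write_graphml(g, path)


def build_consensus(edge_sets, min_methods: int = 2,
                    table: OtuTable | None = None,
                    dataset: str | None = None) -> ConsensusNetwork:
    """Vote edges across methods and weight them by averaged correlation.

    An edge is kept iff supported by at least ``min_methods`` edge sets; its
    weight is the mean coefficient over coefficient-bearing supporters (the
    mb graph votes without a coefficient), its sign follows the weight when
    coefficients exist and the mb sign otherwise, and ``sign_conflict`` marks
    supporter disagreement.  Node attributes (taxonomy, av.ra, prevalence)
    are taken from ``table`` when given; the node set is the full filtered
    OTU universe, so isolated OTUs remain queryable.
    """
    edge_sets = list(edge_sets)
    if len(edge_sets) < 2:
        raise InvalidArgumentError("consensus needs at least 2 edge sets")
    if min_methods < 2:
        raise InvalidArgumentError("min_methods must be >= 2")
    for a in range(len(edge_sets)):
        for b in range(a + 1, len(edge_sets)):
            if not (edge_sets[a].universe & edge_sets[b].universe):
                raise InvalidArgumentError(
                    f"edge sets {edge_sets[a].method!r} and "
                    f"{edge_sets[b].method!r} have disjoint OTU universes")

    votes: dict = {}
    for es in edge_sets:
        for pair, (sign, coef) in es.edges.items():
            votes.setdefault(pair, []).append((es.method, sign, coef))

    g = nx.Graph()
    universe = sorted(set().union(*(es.universe for es in edge_sets)))
    if table is not None:
        for otu in universe:
            attrs = {r: str(table.taxonomy.at[otu, r]) for r in RANKS
                     if otu in table.taxonomy.index}
            g.add_node(otu, av_ra=float(table.av_ra.get(otu, np.nan)),
                       prevalence=float(table.prevalence.get(otu, np.nan)),
                       dataset=dataset or "", **attrs)
    else:
        g.add_nodes_from(universe)

    for pair in sorted(votes):
        supporters = votes[pair]
        if len(supporters) < min_methods:
            continue
        coefs = [c for _, _, c in supporters if c is not None]
        signs = [s for _, s, _ in supporters]
        if coefs:
            weight = float(np.mean(coefs))
            sign = 1 if weight >= 0 else -1
        else:
            weight = float("nan")
            sign = signs[0]
        g.add_edge(*pair, weight=weight, sign=sign,
                   methods=sorted(m for m, _, _ in supporters),
                   sign_conflict=len(set(signs)) > 1)
    return ConsensusNetwork(g, min_methods=min_methods)


@dataclass
class RecoveryMetrics:
    """Precision/recall of a predicted edge set against the planted truth."""

    precision: float
    recall: float
    f1: float
    sign_accuracy: float
    n_true: int
    n_predicted: int
    n_tp: int
    note: str = ""


def evaluate_recovery(network: ConsensusNetwork,
                      truth: synthetic.TruthNetwork) -> RecoveryMetrics:
    """Score consensus edges against planted edges over unordered pairs.

    Empty truth and empty prediction score 1 by convention; an empty
    prediction against non-empty truth has undefined precision (NaN, noted)
    and recall 0.  Sign accuracy is computed over true-positive edges.
    """
    pred = network.edge_pairs()
    true_pairs = truth.edge_pairs()
    true_signs = truth.signed_pairs()
    tp = pred & true_pairs
    note = ""
    if not true_pairs and not pred:
        precision = recall = f1 = sign_acc = 1.0
        note = "empty truth and prediction; metrics 1 by convention"
        return RecoveryMetrics(precision, recall, f1, sign_acc, 0, 0, 0, note)
    precision = len(tp) / len(pred) if pred else (1.0 if not true_pairs
                                                  else float("nan"))
    if not pred and true_pairs:
        note = "empty prediction; precision undefined"
    recall = len(tp) / len(true_pairs) if true_pairs else 1.0
    if precision and recall and not np.isnan(precision) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if pred or true_pairs else 1.0
    if tp:
        ok = sum(1 for pair in tp
                 if network.graph.edges[pair]["sign"] == true_signs[pair])
        sign_acc = ok / len(tp)
    else:
        sign_acc = float("nan")
    return RecoveryMetrics(precision, recall, f1, sign_acc,
                           len(true_pairs), len(pred), len(tp), note)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class SparccParams:
    max_iter: int = 100
    th: float = 0.1
    exiter: int = 10
    n_boot: int = 100


@dataclass
class MbParams:
    nlambda: int = 20
    lambda_min_ratio: float = 1e-2
    n_reps: int = 50
    beta: float = 0.05


#: Method trios per dataset tag, as run on the study's two tables.
DEFAULT_METHODS = {"TS": ("pearson", "sparcc", "mb"),
                   "MC": ("pearson", "dice", "mb")}

#: Rarefaction depths per dataset tag (reads per sample / culture).
DEFAULT_DEPTHS = {"TS": 1500, "MC": 500}


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with study defaults."""

    dataset: str = "TS"
    # synthetic community (used when no table is supplied)
    n_otus: int = 100
    n_phyla: int = 6
    n_samples: int = 200              # TS samples, or MC cultures
    n_edges: int = 30
    strength: float = 0.8
    frac_negative: float = 0.25
    assortative_bias: float = 0.0
    noise_sd: float = 0.5
    seasonal_amplitude_max: float = 0.6
    depth: int | None = None          # None -> 1500 (TS) / 500 (MC)
    # rare-OTU filtering
    filter_mode: str = "sweep"        # "sweep" | "preset" | "none"
    min_samples_grid: tuple = (2, 5, 10, 15, 20, 25, 29, 35, 40, 46)
    total_ra_count_grid: tuple = (1, 5, 10, 25, 50, 100, 150)
    # estimators
    methods: tuple | None = None      # None -> trio for the dataset
    sparcc: SparccParams = field(default_factory=SparccParams)
    mb: MbParams = field(default_factory=MbParams)
    compute_sparcc_pvalues: bool = False
    # consensus
    min_abs_coef: float = 0.3
    inclusive_threshold: bool = False
    min_methods: int = 2
    max_p_adj: float | None = None
    seed: int = 1
    out_dir: str | None = None

    def resolved_depth(self) -> int:
        return self.depth if self.depth is not None else DEFAULT_DEPTHS[self.dataset]

    def resolved_methods(self) -> tuple:
        m = self.methods if self.methods is not None else DEFAULT_METHODS[self.dataset]
        if len(m) < 2:
            raise InvalidArgumentError("consensus needs at least 2 methods")
        return tuple(m)

    def validate(self) -> None:
        if self.dataset not in ("TS", "MC"):
            raise InvalidArgumentError("dataset must be 'TS' or 'MC'")
        self.resolved_methods()
        if self.min_methods < 2:
            raise InvalidArgumentError("min_methods must be >= 2")


def run_pipeline(config: PipelineConfig, table: OtuTable | None = None,
                 truth: synthetic.TruthNetwork | None = None):
    """Run rarefaction -> filtering -> estimators -> consensus -> statistics.

    With no ``table``, a synthetic dataset is generated from the config (and
    recovery against its planted truth is reported).  Returns
    ``(ConsensusNetwork, reports)`` where ``reports`` collects intermediates:
    filter outcome, per-method results, StARS state, network statistics and
    recovery metrics.  Identical config + seed gives byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=8)
    reports: dict = {"config": config}

    if table is None:
        taxa = synthetic.make_taxonomy(config.n_otus, config.n_phyla, int(sub[0]))
        truth = synthetic.make_truth_network(
            taxa, config.n_edges, frac_negative=config.frac_negative,
            strength=config.strength, assortative_bias=config.assortative_bias,
            amplitude_max=config.seasonal_amplitude_max, seed=int(sub[1]))
        if config.dataset == "TS":
            table = synthetic.simulate_timeseries(
                taxa, truth, config.n_samples, depth=config.resolved_depth(),
                noise_sd=config.noise_sd, seed=int(sub[2]))
        else:
            comp = np.exp(truth.base_log_abundance)
            expt = synthetic.simulate_cultures(
                taxa, truth, comp / comp.sum(), n_cultures=config.n_samples,
                depth=config.resolved_depth(), seed=int(sub[2]))
            table = expt.table.select_samples(
                expt.detected.index[expt.detected])
            reports["culture_experiment"] = expt
        reports["truth"] = truth
        reports["taxonomy"] = taxa

    depth = config.resolved_depth()
    table = rarefy(table, depth, int(sub[3]))
    reports["rarefied_summary"] = summarize(table)

    if config.dataset == "MC":
        filtered = drop_singletons(table)
        reports["filter"] = "drop_singletons"
    elif config.filter_mode == "sweep":
        sweep = filter_sweep(table, config.min_samples_grid,
                             [c / depth for c in config.total_ra_count_grid])
        filtered = sweep.table
        reports["filter"] = sweep
    elif config.filter_mode == "preset":
        filtered = apply_filter(table, ts_filter_preset())
        reports["filter"] = ts_filter_preset()
    else:
        filtered = table
        reports["filter"] = "none"
    if filtered.n_otus < 4:
        raise InvalidArgumentError("fewer than 4 OTUs left after filtering")
    reports["filtered_table"] = filtered

    results = {}
    for method in config.resolved_methods():
        if method == "pearson":
            results[method] = pearson_matrix(filtered)
        elif method == "sparcc":
            sp = config.sparcc
            if config.compute_sparcc_pvalues:
                res, state = sparcc_with_pvalues(
                    filtered, max_iter=sp.max_iter, th=sp.th, exiter=sp.exiter,
                    n_boot=sp.n_boot, seed=int(sub[4]))
            else:
                res, state = sparcc(filtered, max_iter=sp.max_iter, th=sp.th,
                                    exiter=sp.exiter, seed=int(sub[4]))
            results[method] = res
            reports["sparcc_state"] = state
        elif method == "dice":
            results[method] = dice_sorensen(filtered)
        elif method == "mb":
            mp = config.mb
            res, stars = mb_network(filtered, nlambda=mp.nlambda,
                                    lambda_min_ratio=mp.lambda_min_ratio,
                                    n_reps=mp.n_reps, beta=mp.beta,
                                    seed=int(sub[5]))
            results[method] = res
            reports["stars_state"] = stars
        else:
            raise InvalidArgumentError(f"unknown method {method!r}")
    reports["method_results"] = results

    edge_sets = [threshold_edges(results[m], min_abs_coef=config.min_abs_coef,
                                 inclusive=config.inclusive_threshold,
                                 max_p_adj=config.max_p_adj)
                 for m in config.resolved_methods()]
    network = build_consensus(edge_sets, min_methods=config.min_methods,
                              table=filtered, dataset=config.dataset)
    reports["edge_sets"] = edge_sets

    from . import netstats  # local import: netstats depends on this module
    if network.n_edges > 0:
        reports["assortativity"] = {
            rank: netstats.nominal_assortativity(network, rank)
            for rank in ("phylum", "class", "order", "family", "genus")}
        partition, q = netstats.modularity_stats(network)
        reports["modularity"] = q
        reports["partition"] = partition
    if truth is not None:
        reports["recovery"] = evaluate_recovery(network, truth)

    if config.out_dir is not None:
        _write_outputs(Path(config.out_dir), config, network, results, reports)
    return network, reports


def _write_outputs(out: Path, config: PipelineConfig, network: ConsensusNetwork,
                   results: dict, reports: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    network.write_tsv(out / "consensus_edges.tsv")
    network.write_graphml(out / "consensus.graphml")
    for method, res in results.items():
        res.to_long().to_csv(out / f"{method}_edges.tsv", sep="\t", index=False)
    reports["filtered_table"].to_tsv(out / "filtered_table.tsv")
    cfg = asdict(config)
    with open(out / "pipeline_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    logger.info("pipeline outputs written to %s", out)
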