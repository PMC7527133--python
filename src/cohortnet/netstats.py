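"""Topological and taxonomic statistics on the consensus network.

Covers Newman's nominal assortativity per taxonomic rank (do edges
preferentially connect OTUs sharing a label?), greedy modularity
communities, extraction of a target taxon's first neighbors (its "primary
cohort"), and cohort overlap/sign comparison across datasets.  Edge signs
are ignored for assortativity and modularity; both operate on the unsigned,
unweighted consensus graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork
from .otu_table import InvalidArgumentError, RANKS


def nominal_assortativity(network: ConsensusNetwork, rank: str,
                          labels: dict | None = None) -> float:
    """Newman's nominal assortativity of edges for labels at ``rank``.

    From the edge-endpoint label mixing matrix e (each undirected edge
    counted once in each direction)::

        r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)

    Returns NaN when the network carries a single label (denominator 0).
    ``labels`` overrides the node attribute lookup (mapping node -> label),
    which otherwise reads the taxonomy attribute stored at ``rank``.
    """
    g = network.graph if isinstance(network, ConsensusNetwork) else network
    if g.number_of_edges() == 0:
        raise InvalidArgumentError("assortativity needs at least one edge")
    if labels is None:
        if rank not in RANKS:
            raise InvalidArgumentError(f"unknown rank {rank!r}")
        labels = {n: g.nodes[n].get(rank) for n in g.nodes}
    cats = sorted({labels[n] for e in g.edges for n in e}, key=str)
    index = {c: k for k, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in g.edges:
        a, b = index[labels[u]], index[labels[v]]
        e[a, b] += 1
        e[b, a] += 1
    e /= e.sum()
    ai = e.sum(axis=1)
    bi = e.sum(axis=0)
    denom = 1.0 - float(ai @ bi)
    if abs(denom) < 1e-15:
        return float("nan")
    return (float(np.trace(e)) - float(ai @ bi)) / denom


def modularity_stats(network: ConsensusNetwork):
    """Greedy modularity-maximizing partition and its Q on the unsigned graph.

    Q = sum_c (e_cc - a_c^2) over communities, computed by networkx on the
    unweighted consensus graph after greedy agglomerative community search.
    """
    g = network.graph if isinstance(network, ConsensusNetwork) else network
    if g.number_of_edges() == 0:
        raise InvalidArgumentError("modularity needs at least one edge")
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges)
    communities = list(nx.community.greedy_modularity_communities(h))
    q = nx.community.modularity(h, communities)
    return [frozenset(c) for c in communities], float(q)


@dataclass
class Cohort:
    """A target taxon set and its signed first neighbors (1-degree cohort)."""

    target: frozenset
    neighbors: dict                   # otu -> (sign, weight) of strongest edge
    dataset: str = ""
    subgraph: nx.Graph | None = None
    name: str = ""

    def neighbor_set(self) -> set:
        return set(self.neighbors)

    def to_df(self) -> pd.DataFrame:
        rows = [dict(otu=o, sign=s, weight=w)
                for o, (s, w) in sorted(self.neighbors.items())]
        return pd.DataFrame(rows, columns=["otu", "sign", "weight"])


def first_neighbors(network: ConsensusNetwork, target,
                    dataset: str = "", name: str = "") -> Cohort:
    """All non-target nodes adjacent to any target node.

    Each neighbor is annotated with the sign and weight of its
    strongest-|weight| edge to the target set; the returned cohort also
    carries the induced subnetwork over target plus neighbors.
    """
    g = network.graph
    target = frozenset(target)
    missing = sorted(t for t in target if t not in g)
    if missing:
        raise InvalidArgumentError(f"target OTUs not in network: {missing}")
    neighbors: dict = {}
    for t in target:
        for nb in g.neighbors(t):
            if nb in target:
                continue
            d = g.edges[t, nb]
            w = d.get("weight", float("nan"))
            s = d.get("sign", 1)
            best = neighbors.get(nb)
            mag = abs(w) if w == w else 0.0      # NaN-safe magnitude
            if best is None or mag > best[2]:
                neighbors[nb] = (s, w, mag)
    annotated = {nb: (s, w) for nb, (s, w, _) in neighbors.items()}
    sub = g.subgraph(target | set(annotated)).copy()
    return Cohort(target, annotated, dataset=dataset, subgraph=sub, name=name)


@dataclass
class CohortOverlap:
    """Directional shared-neighbor fractions and sign agreement per pair."""

    fractions: pd.DataFrame           # fractions.loc[A, B] = |A & B| / |A|
    shared: dict                      # (nameA, nameB) -> set of shared OTUs
    sign_agreement: dict              # (nameA, nameB) -> fraction agreeing
    common_to_all: set = field(default_factory=set)


def cohort_overlap(cohorts) -> CohortOverlap:
    """Pairwise overlap structure of two or more cohorts.

    ``fractions.loc[A, B]`` is the fraction of A's neighbors shared with B
    (NaN for an empty A, flagged rather than raising); ``sign_agreement``
    reports, per ordered pair, the fraction of shared neighbors whose edge
    sign to the two targets agrees.
    """
    cohorts = list(cohorts)
    if len(cohorts) < 2:
        raise InvalidArgumentError("need at least 2 cohorts")
    names = []
    for k, c in enumerate(cohorts):
        names.append(c.name or f"cohort{k + 1}")
    frac = pd.DataFrame(np.nan, index=names, columns=names)
    shared: dict = {}
    agree: dict = {}
    sets = {nm: c.neighbor_set() for nm, c in zip(names, cohorts)}
    signs = {nm: {o: s for o, (s, _) in c.neighbors.items()}
             for nm, c in zip(names, cohorts)}
    for na in names:
        for nb in names:
            if na == nb:
                frac.loc[na, nb] = 1.0 if sets[na] else np.nan
                continue
            inter = sets[na] & sets[nb]
            shared[(na, nb)] = inter
            frac.loc[na, nb] = (len(inter) / len(sets[na])
                                if sets[na] else np.nan)
            if inter:
                ok = sum(1 for o in inter if signs[na][o] == signs[nb][o])
                agree[(na, nb)] = ok / len(inter)
            else:
                agree[(na, nb)] = float("nan")
    common = set.intersection(*sets.values()) if sets else set()
    return CohortOverlap(frac, shared, agree, common)
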