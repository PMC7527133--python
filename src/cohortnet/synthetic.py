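"""Seeded synthetic communities with planted interactions.

This module generates datasets with the statistical structure the network
pipeline assumes, so every downstream stage can be tested against a known
ground truth without any sequence data:

* a 7-rank taxonomy over OTUs backed by an ultrametric tree (pairwise
  patristic distances included),
* a planted signed interaction network (the "truth" the estimators should
  recover),
* lake time-series count tables: compositional multinomial counts at an even
  depth driven by latent log-abundances (baseline + clade-structured seasonal
  sinusoid + per-edge latent coupling + noise),
* dilution mixed-culture count tables: ~10 founder cells per 1-ml culture
  drawn from a lake composition, growth limited by culturability (and
  optionally by obligate positive-edge partners), with detection censoring
  that emulates the study design of 98 cultures yielding ~60 usable ones,
* environmental covariate tables with seasonal + AR(1) structure, optional
  planted taxon links, and missing values.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .otu_table import RANKS, InvalidArgumentError, OtuTable

# Node heights of the internal nodes backing each rank, in arbitrary
# ultrametric time units (root = domain at height 1).  Fixed heights keep the
# tree ultrametric and make patristic distance a deterministic function of
# the deepest shared rank.
RANK_HEIGHTS = {
    "domain": 1.0,
    "phylum": 0.78,
    "class": 0.58,
    "order": 0.42,
    "family": 0.28,
    "genus": 0.15,
}


@dataclass
class TaxonomySet:
    """OTU identifiers, 7-rank labels, ultrametric tree and patristic distances."""

    otu_ids: list
    ranks: pd.DataFrame              # OTUs x RANKS
    tree: dendropy.Tree
    pd_matrix: pd.DataFrame          # pairwise patristic distance

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick")


@dataclass
class TruthNetwork:
    """Planted signed OTU-OTU interactions plus per-OTU dynamic parameters."""

    edges: list                      # (otu_i, otu_j, sign(+1/-1), strength)
    base_log_abundance: pd.Series
    seasonal_amplitude: pd.Series
    seasonal_phase: pd.Series        # radians

    def edge_pairs(self) -> set:
        """Unordered OTU id pairs as sorted tuples."""
        return {tuple(sorted((i, j))) for i, j, _, _ in self.edges}

    def signed_pairs(self) -> dict:
        return {tuple(sorted((i, j))): s for i, j, s, _ in self.edges}

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.edges, columns=["otu_i", "otu_j", "sign", "strength"])
        df["sign"] = df["sign"].map({1: "+", -1: "-"})
        df.to_csv(path, sep="\t", index=False)


@dataclass
class EnvTable:
    """Environmental parameters per sample; NaN marks a missing measurement."""

    values: pd.DataFrame             # samples x parameters

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class CultureExperiment:
    """A dilution mixed-culture run: counts plus the founding ground truth."""

    table: OtuTable                  # counts for all cultures (incl. excluded)
    founders: pd.DataFrame           # cultures x OTUs founder-cell counts
    detected: pd.Series              # per-culture bool: passed detection
    excluded: list = field(default_factory=list)

    def founder_occupancy(self) -> pd.Series:
        """Fraction of cultures founded by at least one cell of each OTU."""
        return (self.founders > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def _random_partition(members: np.ndarray, n_parts: int, rng) -> list:
    """Split ``members`` into ``n_parts`` non-empty groups uniformly at random."""
    members = rng.permutation(members)
    if n_parts <= 1 or len(members) == 1:
        return [members]
    cuts = rng.choice(np.arange(1, len(members)), size=n_parts - 1, replace=False)
    return np.split(members, np.sort(cuts))


def make_taxonomy(n_otus: int, n_phyla: int, seed: int) -> TaxonomySet:
    """Generate OTUs in a random nested 7-rank hierarchy with a matching tree.

    OTUs sharing a label at any rank are monophyletic by construction; the
    tree is ultrametric with internal-node heights fixed per rank
    (:data:`RANK_HEIGHTS`), so the maximum patristic distance equals twice
    the tree height whenever more than one phylum exists.
    """
    if n_otus < 1 or n_phyla < 1 or n_otus < n_phyla:
        raise InvalidArgumentError("need n_otus >= n_phyla >= 1")
    rng = np.random.default_rng(seed)
    otu_ids = [f"otu{i:04d}" for i in range(n_otus)]
    labels = pd.DataFrame(index=otu_ids, columns=list(RANKS), dtype=object)
    labels["domain"] = "Bacteria"

    # phylum: guarantee every phylum non-empty, the rest uniform
    groups = _random_partition(np.arange(n_otus), n_phyla, rng)
    for g, members in enumerate(groups):
        labels.iloc[members, labels.columns.get_loc("phylum")] = f"p{g + 1}"

    sub_ranks = ["class", "order", "family", "genus"]
    for rank_i, rank in enumerate(sub_ranks):
        parent_rank = (["phylum"] + sub_ranks)[rank_i]
        for parent_label, idx in labels.groupby(parent_rank).groups.items():
            members = labels.index.get_indexer(idx)
            k = int(min(len(members), 1 + rng.poisson(0.7)))
            for g, part in enumerate(_random_partition(members, k, rng)):
                col = labels.columns.get_loc(rank)
                labels.iloc[part, col] = f"{parent_label}_{rank[0]}{g + 1}"
    labels["species"] = [f"{o}_sp" for o in otu_ids]

    # patristic distances from the deepest shared rank
    pdm = np.full((n_otus, n_otus), 2.0 * RANK_HEIGHTS["domain"])
    for rank in ("phylum", "class", "order", "family", "genus"):
        codes = pd.factorize(labels[rank])[0]
        same = codes[:, None] == codes[None, :]
        pdm[same] = 2.0 * RANK_HEIGHTS[rank]
    np.fill_diagonal(pdm, 0.0)
    pd_matrix = pd.DataFrame(pdm, index=otu_ids, columns=otu_ids)

    tree = _build_tree(labels, otu_ids)
    return TaxonomySet(otu_ids, labels, tree, pd_matrix)


def _build_tree(labels: pd.DataFrame, otu_ids: list) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(otu_ids)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node.label = "Bacteria"

    def grow(node, rank_idx, members):
        height = RANK_HEIGHTS[("domain", "phylum", "class", "order", "family",
                               "genus")[rank_idx]]
        if rank_idx == 5:  # genus node: attach leaves
            for otu in members:
                leaf = node.new_child(edge_length=height)
                leaf.taxon = ns.get_taxon(otu)
            return
        child_rank = ("phylum", "class", "order", "family", "genus")[rank_idx]
        child_height = RANK_HEIGHTS[child_rank]
        for lab, group in labels.loc[members].groupby(child_rank, sort=True):
            child = node.new_child(edge_length=height - child_height)
            child.label = str(lab)
            grow(child, rank_idx + 1, list(group.index))

    grow(tree.seed_node, 0, otu_ids)
    return tree


# ---------------------------------------------------------------------------
# truth network
# ---------------------------------------------------------------------------


def make_truth_network(
    taxa: TaxonomySet,
    n_edges: int,
    frac_negative: float = 0.25,
    strength: float = 0.8,
    assortative_bias: float = 0.0,
    seed: int = 0,
    base_sd: float = 1.2,
    amplitude_max: float = 0.6,
    phase_jitter: float = 0.5,
) -> TruthNetwork:
    """Plant ``n_edges`` signed interactions among the OTUs.

    With ``assortative_bias > 0`` within-phylum pairs are oversampled (their
    sampling weight is multiplied by ``exp(assortative_bias)``), emulating
    taxonomic assortativity.  Each edge carries the common ``strength`` in
    (0, 1] and is negative with probability ``frac_negative``.

    Baseline log-abundances, seasonal amplitudes and clade-structured seasonal
    phases (a shared phylum phase plus jitter) are drawn here because they are
    part of the planted ground truth the time-series simulator realizes.
    """
    n = taxa.n_otus
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise InvalidArgumentError(f"requested {n_edges} edges but only "
                                   f"{max_edges} pairs exist")
    if not 0.0 <= frac_negative <= 1.0:
        raise InvalidArgumentError("frac_negative must be in [0, 1]")
    if not 0.0 < strength <= 1.0:
        raise InvalidArgumentError("strength must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = taxa.otu_ids
    edges = []
    if n_edges > 0:
        iu, ju = np.triu_indices(n, k=1)
        phyl = pd.factorize(taxa.ranks["phylum"])[0]
        w = np.where(phyl[iu] == phyl[ju], np.exp(assortative_bias), 1.0)
        pick = rng.choice(len(iu), size=n_edges, replace=False, p=w / w.sum())
        signs = np.where(rng.random(n_edges) < frac_negative, -1, 1)
        edges = [(ids[iu[k]], ids[ju[k]], int(s), float(strength))
                 for k, s in zip(pick, signs)]

    phylum_phase = {p: rng.uniform(0, 2 * np.pi)
                    for p in taxa.ranks["phylum"].unique()}
    phase = pd.Series(
        [phylum_phase[p] + rng.normal(0, phase_jitter)
         for p in taxa.ranks["phylum"]], index=ids, name="phase")
    return TruthNetwork(
        edges=edges,
        base_log_abundance=pd.Series(rng.normal(0, base_sd, n), index=ids,
                                     name="base"),
        seasonal_amplitude=pd.Series(rng.uniform(0, amplitude_max, n), index=ids,
                                     name="amplitude"),
        seasonal_phase=phase,
    )


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

_SEASON_BY_MONTH = {12: "winter", 1: "winter", 2: "winter",
                    3: "spring", 4: "spring", 5: "spring",
                    9: "autumn", 10: "autumn", 11: "autumn"}


def _phase_labels(dates: pd.DatetimeIndex) -> list:
    """Season per date; summer samples cycle through the stratified layers."""
    labels, layer = [], 0
    for d in dates:
        if d.month in (6, 7, 8):
            labels.append(("epilimnion", "metalimnion", "hypolimnion")[layer % 3])
            layer += 1
        else:
            labels.append(_SEASON_BY_MONTH[d.month])
    return labels


def simulate_timeseries(
    taxa: TaxonomySet,
    truth: TruthNetwork,
    n_samples: int,
    depth: int = 1500,
    noise_sd: float = 0.5,
    seed: int = 0,
    coupling_scale: float = 1.5,
    start: str = "2007-02-05",
) -> OtuTable:
    """Weekly lake samples as multinomial counts at an even depth.

    Latent log-abundance of OTU *i* in sample *s* is::

        l_is = base_i + amp_i * sin(2*pi*t_s + phi_i) + coupling + eps_is

    where the coupling term adds, for every planted edge, a shared standard
    Gaussian factor scaled by ``coupling_scale * strength`` — in phase for
    positive edges, in anti-phase for negative ones — and ``eps`` is Gaussian
    with ``noise_sd``.  Counts are multinomial(depth, softmax(l)) per sample,
    so every sample sums to exactly ``depth``.
    """
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    if n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    ids = taxa.otu_ids
    dates = pd.date_range(start, periods=n_samples, freq="7D")
    t = np.arange(n_samples) * 7.0 / 365.25

    latent = (truth.base_log_abundance[ids].to_numpy()[None, :]
              + truth.seasonal_amplitude[ids].to_numpy()[None, :]
              * np.sin(2 * np.pi * t[:, None]
                       + truth.seasonal_phase[ids].to_numpy()[None, :]))
    col = {o: k for k, o in enumerate(ids)}
    for i, j, sign, strength in truth.edges:
        f = rng.normal(0, 1, n_samples) * coupling_scale * strength
        latent[:, col[i]] += f
        latent[:, col[j]] += sign * f
    latent += rng.normal(0, noise_sd, latent.shape)

    p = np.exp(latent - latent.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p[s]) for s in range(n_samples)])

    sample_ids = [f"ts{s:04d}" for s in range(n_samples)]
    meta = pd.DataFrame({"date": dates, "phase": _phase_labels(dates),
                         "dataset": "TS"}, index=sample_ids)
    table = pd.DataFrame(counts, index=sample_ids, columns=ids)
    return OtuTable(table, taxa.ranks.copy(), meta)


# ---------------------------------------------------------------------------
# dilution mixed cultures
# ---------------------------------------------------------------------------


def simulate_cultures(
    taxa: TaxonomySet,
    truth: TruthNetwork,
    lake_composition: pd.Series,
    n_cultures: int = 98,
    founder_mean: float = 10.0,
    depth: int = 500,
    detection_fraction: float = 0.5,
    seed: int = 0,
    culturable_mass_fraction: float = 0.095,
    growth_factor: float = 1e4,
    growth_noise_sd: float = 0.5,
    obligate_edges=None,
) -> CultureExperiment:
    """Dilution-to-few-cells mixed cultures with detection censoring.

    Each of ``n_cultures`` 1-ml cultures is founded by Poisson(``founder_mean``)
    cells assigned to OTUs by ``lake_composition``.  A founded OTU grows (by
    ``growth_factor`` with lognormal noise) only if it is culturable in the
    medium, and, when ``obligate_edges`` lists obligate positive partnerships,
    only if all its obligate partners were also founded; otherwise it stays
    at founder level.  The culturable taxa are a random subset chosen to
    hold approximately ``culturable_mass_fraction`` of the inoculum mass
    (most freshwater taxa do not grow in filtered-water media; what matters
    for the censoring yield is the culturable share of cells, not of taxa).
    Counts are multinomial over grown biomass at ``depth`` reads.

    A culture is *detected* when its total grown biomass reaches
    ``detection_fraction * growth_factor`` (a fraction of one fully grown
    founder's yield).  At the defaults the detection probability is about
    1 - exp(-founder_mean * culturable_mass_fraction) deflated slightly by
    growth noise, i.e. ~0.6, censoring roughly 60 of 98 cultures into the
    detected set.  Undetected cultures stay in the table but are flagged
    ``detected=False`` and listed in ``excluded``.
    """
    comp = lake_composition.astype(float)
    if abs(comp.sum() - 1.0) > 1e-8 or (comp < 0).any():
        raise InvalidArgumentError("lake_composition must be a probability vector")
    if founder_mean <= 0:
        raise InvalidArgumentError("founder_mean must be > 0")
    rng = np.random.default_rng(seed)
    ids = list(comp.index)
    n_otus = len(ids)

    # greedy mass-targeted culturable set: walk taxa in random order and
    # include one whenever that moves the culturable mass closer to target
    target = culturable_mass_fraction
    culturable = np.zeros(n_otus, dtype=bool)
    mass = 0.0
    weights = comp.to_numpy()
    for k in rng.permutation(n_otus):
        if abs(mass + weights[k] - target) < abs(mass - target):
            culturable[k] = True
            mass += weights[k]
    obligate = {}
    if obligate_edges:
        for a, b in obligate_edges:
            obligate.setdefault(a, set()).add(b)
            obligate.setdefault(b, set()).add(a)

    founders = np.zeros((n_cultures, n_otus), dtype=np.int64)
    for c in range(n_cultures):
        n_cells = rng.poisson(founder_mean)
        if n_cells > 0:
            founders[c] = rng.multinomial(n_cells, comp.to_numpy())

    founded = founders > 0
    idx = {o: k for k, o in enumerate(ids)}
    biomass = founders.astype(float)
    grown_mask = np.zeros_like(founded)
    for k, otu in enumerate(ids):
        grows = founded[:, k] & culturable[k]
        partners = obligate.get(otu)
        if partners:
            for p in partners:
                grows = grows & founded[:, idx[p]]
        grown_mask[:, k] = grows
    noise = np.exp(rng.normal(0, growth_noise_sd, biomass.shape))
    biomass = np.where(grown_mask, biomass * growth_factor * noise, biomass)

    grown_total = (biomass * grown_mask).sum(axis=1)
    detected = grown_total >= detection_fraction * growth_factor

    counts = np.zeros((n_cultures, n_otus), dtype=np.int64)
    for c in range(n_cultures):
        tot = biomass[c].sum()
        if tot > 0:
            counts[c] = rng.multinomial(depth, biomass[c] / tot)

    culture_ids = [f"mc{c:03d}" for c in range(n_cultures)]
    meta = pd.DataFrame({
        "date": pd.Timestamp("2016-03-08"),
        "phase": "culture",
        "dataset": "MC",
        "detected": detected,
        "n_founders": founders.sum(axis=1),
    }, index=culture_ids)
    table = OtuTable(pd.DataFrame(counts, index=culture_ids, columns=ids),
                     taxa.ranks.loc[ids].copy(), meta)
    fdf = pd.DataFrame(founders, index=culture_ids, columns=ids)
    excluded = [c for c, d in zip(culture_ids, detected) if not d]
    return CultureExperiment(table, fdf, pd.Series(detected, index=culture_ids,
                                                   name="detected"), excluded)


# ---------------------------------------------------------------------------
# environmental covariates
# ---------------------------------------------------------------------------


def simulate_env(
    n_samples: int,
    n_params: int = 14,
    linked_otus=(),
    link_r: float = 0.0,
    missing_frac: float = 0.0,
    seed: int = 0,
    table: OtuTable | None = None,
    ar_coef: float = 0.7,
) -> EnvTable:
    """Environmental parameters: seasonal sinusoid + AR(1) noise.

    For every OTU in ``linked_otus`` (which must be columns of ``table``), one
    parameter is constructed with target Pearson correlation ``link_r`` to
    that OTU's relative abundance; the remaining parameters are unlinked.
    Missing entries are inserted independently at rate ``missing_frac``.
    """
    if not 0.0 <= missing_frac < 1.0:
        raise InvalidArgumentError("missing_frac must be in [0, 1)")
    if abs(link_r) >= 1.0 and linked_otus:
        raise InvalidArgumentError("|link_r| must be < 1")
    linked_otus = list(linked_otus)
    if len(linked_otus) > n_params:
        raise InvalidArgumentError("more linked OTUs than parameters")
    if linked_otus and table is None:
        raise InvalidArgumentError("linked OTUs require the OTU table")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * 7.0 / 365.25

    def base_series() -> np.ndarray:
        amp, phi = rng.uniform(0.5, 2.0), rng.uniform(0, 2 * np.pi)
        ar = np.empty(n_samples)
        ar[0] = rng.normal()
        innov = rng.normal(0, 1, n_samples)
        for s in range(1, n_samples):
            ar[s] = ar_coef * ar[s - 1] + innov[s]
        x = amp * np.sin(2 * np.pi * t + phi) + ar
        return (x - x.mean()) / x.std()

    if table is not None:
        index = table.counts.index[:n_samples]
        if len(index) < n_samples:
            raise InvalidArgumentError("table has fewer samples than requested")
    else:
        index = pd.Index([f"ts{s:04d}" for s in range(n_samples)])

    cols = {}
    for k, otu in enumerate(linked_otus):
        ra = table.proportions[otu].to_numpy()[:n_samples]
        z = (ra - ra.mean()) / ra.std()
        w = base_series()
        w = w - z * (w @ z) / (z @ z)          # orthogonalize for exact target r
        w = w / w.std()
        cols[f"param{k + 1:02d}_{otu}"] = (
            link_r * z + np.sqrt(1 - link_r ** 2) * w)
    for k in range(len(linked_otus), n_params):
        cols[f"param{k + 1:02d}"] = base_series()

    values = pd.DataFrame(cols, index=index)
    if missing_frac > 0:
        mask = rng.random(values.shape) < missing_frac
        values = values.mask(mask)
    return EnvTable(values)
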