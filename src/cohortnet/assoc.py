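"""Non-network statistical screens.

Environmental collinearity pruning (missingness, VIF, pairwise correlation),
the Pearson environment-taxon screen at alpha 0.001 with BH adjustment,
season/layer Kruskal-Wallis with a critical-difference post hoc
(mean-rank-sum comparison), phylogenetic-distance-versus-correlation
analysis within a cohort, and cross-dataset abundance/prevalence
correlations between the lake time series and the mixed cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusNetwork
from .netstats import Cohort
from .otu_table import InvalidArgumentError, OtuTable
from .synthetic import EnvTable


@dataclass
class AssocResult:
    """One screened association: a labelled statistic with raw/adjusted p."""

    label: str
    statistic: float
    p_raw: float
    p_adj: float = float("nan")
    n: int = 0
    flag_passed: bool = False
    detail: dict = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p on paired finite observations."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# collinearity pruning
# ---------------------------------------------------------------------------


@dataclass
class CollinearityReport:
    """What was removed, in order and why; the retained parameter set."""

    removed: list                      # (param, reason) in removal order
    retained: list
    vif: pd.Series                     # final VIFs of the retained set
    max_abs_corr: float


def _vif(values: pd.DataFrame) -> pd.Series:
    """VIF = 1/(1 - R^2) regressing each parameter on the others (complete cases)."""
    cc = values.dropna()
    if cc.shape[0] < 2:
        raise InvalidArgumentError("fewer than 2 complete-case rows")
    x = cc.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    out = {}
    for k, name in enumerate(values.columns):
        y = x[:, k]
        others = np.delete(x, k, axis=1)
        if y.std() == 0:
            out[name] = np.inf
            continue
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - (resid @ resid) / (y @ y)
        out[name] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out)


def prune_collinear(env: EnvTable, missing_cutoff: float = 0.4,
                    vif_cutoff: float = 10.0,
                    corr_cutoff: float = 0.7) -> CollinearityReport:
    """Two-stage environmental parameter pruning.

    Stage 1 removes parameters with more than ``missing_cutoff`` of values
    missing.  Stage 2 iteratively removes, among parameters violating either
    the VIF or the pairwise-|correlation| cutoff, the one with the most
    missing values (ties: highest VIF) until the retained set satisfies both
    constraints.
    """
    values = env.values.copy()
    if values.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 parameters")
    removed = []
    miss = values.isna().mean(axis=0)
    for name in values.columns[miss > missing_cutoff]:
        removed.append((name, f"missingness {miss[name]:.2f} > {missing_cutoff}"))
    values = values.drop(columns=[n for n, _ in removed])

    for _ in range(env.values.shape[1]):
        if values.shape[1] < 2:
            break
        vif = _vif(values)
        corr = values.corr(min_periods=3).abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        viol = set(vif.index[vif > vif_cutoff])
        viol |= set(corr.index[(corr > corr_cutoff).any(axis=1)])
        if not viol:
            break
        nmiss = values[list(viol)].isna().sum(axis=0)
        worst = sorted(viol, key=lambda p: (-nmiss[p], -vif[p], p))[0]
        reason = (f"VIF {vif[worst]:.1f} > {vif_cutoff}" if vif[worst] > vif_cutoff
                  else f"|corr| {corr[worst].max():.2f} > {corr_cutoff}")
        removed.append((worst, reason))
        values = values.drop(columns=[worst])

    final_vif = _vif(values) if values.shape[1] >= 2 else pd.Series(dtype=float)
    corr = values.corr(min_periods=3).abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    return CollinearityReport(removed, list(values.columns), final_vif,
                              float(corr.max().max()) if not corr.empty else 0.0)


# ---------------------------------------------------------------------------
# environment-taxon Pearson screen
# ---------------------------------------------------------------------------


def env_screen(clades: pd.DataFrame, env: EnvTable, alpha: float = 0.001,
               r_min: float = 0.3) -> list:
    """Pearson r per clade x parameter with BH adjustment over all tests.

    Pairwise-complete observations; an association passes the screen iff
    ``|r| > r_min`` and ``p_adj < alpha``.  Constant series give NaN.
    """
    shared = clades.index.intersection(env.values.index)
    if len(shared) < 3:
        raise InvalidArgumentError("need >= 3 shared samples")
    c = clades.loc[shared]
    e = env.values.loc[shared]
    results = []
    for clade in c.columns:
        for param in e.columns:
            r, p, n = _pearson(c[clade].to_numpy(dtype=float),
                               e[param].to_numpy(dtype=float))
            results.append(AssocResult(f"{clade}|{param}", r, p, n=n))
    ps = np.array([a.p_raw for a in results])
    ok = np.isfinite(ps)
    if ok.any():
        adj = np.full_like(ps, np.nan)
        adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
        for a, pa in zip(results, adj):
            a.p_adj = float(pa)
            a.flag_passed = bool(np.isfinite(a.statistic)
                                 and abs(a.statistic) > r_min
                                 and np.isfinite(pa) and pa < alpha)
    return results


# ---------------------------------------------------------------------------
# season/layer Kruskal-Wallis with post hoc comparison
# ---------------------------------------------------------------------------


def _kwmc_pairs(values: np.ndarray, groups: np.ndarray, alpha: float) -> dict:
    """All-pairs mean-rank-sum comparison with the normal critical difference.

    Two groups differ when ``|Rbar_i - Rbar_j|`` exceeds
    ``z_{1 - alpha/(k(k-1))} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j))``.
    """
    ranks = stats.rankdata(values)
    labels = pd.unique(groups)
    k = len(labels)
    n_tot = len(values)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    z = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    differs = {}
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = labels[a], labels[b]
            cd = z * np.sqrt(n_tot * (n_tot + 1) / 12.0
                             * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            differs[(ga, gb)] = abs(mean_rank[ga] - mean_rank[gb]) > cd
    return differs


def phase_kw(clades: pd.DataFrame, phases: pd.Series,
             alpha: float = 0.001) -> list:
    """Kruskal-Wallis per clade over phase groups, with post hoc pairs.

    Groups with fewer than 2 observations are dropped with a warning entry
    in the result detail.  When the omnibus p is below ``alpha``, all phase
    pairs are compared by the critical-difference rule and each result's
    detail reports ``pairs_differ`` plus ``phases_vs_two_plus`` — the phases
    that differ from at least two others.
    """
    phases = phases.loc[clades.index]
    counts = phases.value_counts()
    keep = counts.index[counts >= 2]
    dropped = sorted(set(counts.index) - set(keep))
    mask = phases.isin(keep)
    if len(keep) < 2:
        raise InvalidArgumentError("need >= 2 phase groups with >= 2 obs each")
    results = []
    for clade in clades.columns:
        vals = clades.loc[mask, clade].to_numpy(dtype=float)
        grp = phases[mask].to_numpy()
        samples = [vals[grp == g] for g in keep]
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:           # all values identical
            h, p = 0.0, 1.0
        detail: dict = {"dropped_groups": dropped}
        if p < alpha:
            differs = _kwmc_pairs(vals, grp, alpha)
            detail["pairs_differ"] = sorted(
                [pair for pair, d in differs.items() if d])
            tally: dict = {}
            for (ga, gb), d in differs.items():
                if d:
                    tally[ga] = tally.get(ga, 0) + 1
                    tally[gb] = tally.get(gb, 0) + 1
            detail["phases_vs_two_plus"] = sorted(
                g for g, c in tally.items() if c >= 2)
        results.append(AssocResult(clade, float(h), float(p),
                                   n=int(mask.sum()),
                                   flag_passed=bool(p < alpha), detail=detail))
    return results


# ---------------------------------------------------------------------------
# phylogenetic distance vs correlation
# ---------------------------------------------------------------------------


def pd_vs_correlation(cohort: Cohort, network: ConsensusNetwork,
                      pd_matrix: pd.DataFrame):
    """Patristic distance vs consensus edge weight over cohort edges.

    For each network-connected (target member, cohort neighbor) pair, x is
    their phylogenetic distance and y the consensus edge weight; returns
    ``(AssocResult, scatter_df)``.  With fewer than 3 connected pairs or a
    constant distance, r is NaN (noted, not raised).
    """
    need = set(cohort.target) | cohort.neighbor_set()
    missing = sorted(need - set(pd_matrix.index))
    if missing:
        raise InvalidArgumentError(f"distance matrix lacks OTUs: {missing}")
    g = network.graph
    rows = []
    for t in sorted(cohort.target):
        for nb in sorted(cohort.neighbor_set()):
            if g.has_edge(t, nb):
                rows.append(dict(target=t, neighbor=nb,
                                 pd=float(pd_matrix.at[t, nb]),
                                 weight=float(g.edges[t, nb]["weight"])))
    scatter = pd.DataFrame(rows, columns=["target", "neighbor", "pd", "weight"])
    r, p, n = _pearson(scatter["pd"].to_numpy(), scatter["weight"].to_numpy()) \
        if len(scatter) else (float("nan"), float("nan"), 0)
    note = {}
    if n < 3 or not np.isfinite(r):
        note["undefined"] = "fewer than 3 connected pairs or constant distance"
    res = AssocResult(f"pd_vs_weight[{cohort.name or 'cohort'}]", r, p,
                      n=n, detail=note)
    return res, scatter


# ---------------------------------------------------------------------------
# cross-dataset abundance / prevalence correlations
# ---------------------------------------------------------------------------


def cross_dataset_corr(table_a: OtuTable, table_b: OtuTable,
                       subsets: dict | None = None) -> list:
    """Cross-dataset Pearson correlations over shared OTUs.

    Correlates log10 av.ra and prevalence between the two tables (plus both
    cross combinations of abundance vs prevalence).  OTUs with av.ra 0 in
    either table are excluded from log correlations (recorded in the result
    detail).  ``subsets`` (name -> OTU list) adds the same four tests per
    designated taxon subset; BH adjustment spans all tests.
    """
    shared = [o for o in table_a.counts.columns if o in set(table_b.counts.columns)]
    if len(shared) < 3:
        raise InvalidArgumentError("need >= 3 shared OTUs")
    groups = {"all": shared}
    for name, otus in (subsets or {}).items():
        groups[name] = [o for o in otus if o in set(shared)]

    results = []
    for gname, otus in groups.items():
        if len(otus) < 3:
            results.append(AssocResult(f"{gname}|skipped", float("nan"),
                                       float("nan"), n=len(otus),
                                       detail={"reason": "fewer than 3 OTUs"}))
            continue
        ra_a = table_a.av_ra[otus]
        ra_b = table_b.av_ra[otus]
        prev_a = table_a.prevalence[otus].to_numpy(dtype=float)
        prev_b = table_b.prevalence[otus].to_numpy(dtype=float)
        pos = (ra_a > 0) & (ra_b > 0)
        log_a = np.where(pos, np.log10(ra_a.where(pos)), np.nan)
        log_b = np.where(pos, np.log10(ra_b.where(pos)), np.nan)
        excluded = sorted(np.array(otus)[~pos.to_numpy()])
        tests = {
            "log_avra_vs_log_avra": (log_a, log_b),
            "prevalence_vs_prevalence": (prev_a, prev_b),
            "log_avra_A_vs_prevalence_B": (log_a, prev_b),
            "log_avra_B_vs_prevalence_A": (log_b, prev_a),
        }
        for tname, (x, y) in tests.items():
            r, p, n = _pearson(np.asarray(x, dtype=float),
                               np.asarray(y, dtype=float))
            detail = {"zero_avra_excluded": excluded} if "avra" in tname else {}
            results.append(AssocResult(f"{gname}|{tname}", r, p, n=n,
                                       detail=detail))
    ps = np.array([a.p_raw for a in results])
    ok = np.isfinite(ps)
    if ok.any():
        adj = np.full_like(ps, np.nan)
        adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
        for a, pa in zip(results, adj):
            a.p_adj = float(pa)
    return results
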