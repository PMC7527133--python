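"""Environmental screens, seasonal Kruskal-Wallis, PD-vs-correlation and
cross-dataset comparisons."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortnet import (Cohort, ConsensusNetwork, EnvTable,
                       InvalidArgumentError, collapse_rank, cross_dataset_corr,
                       env_screen, make_taxonomy, make_truth_network,
                       pd_vs_correlation, phase_kw, prune_collinear,
                       simulate_cultures, simulate_env, simulate_timeseries)


def env_of(arr, cols=None, index=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"p{k}" for k in range(arr.shape[1])]
    index = index if index is not None else [f"s{i}" for i in range(arr.shape[0])]
    return EnvTable(pd.DataFrame(arr, columns=cols, index=index))


class TestPruneCollinear:
    def test_orthogonal_parameters_untouched(self):
        rng = np.random.default_rng(1)
        env = env_of(rng.normal(size=(200, 5)))
        report = prune_collinear(env)
        assert report.removed == []
        assert (report.vif < 2.0).all()

    def test_duplicate_parameter_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 3))
        x = np.hstack([x, x[:, [0]]])
        report = prune_collinear(env_of(x))
        assert len(report.removed) == 1
        assert report.max_abs_corr <= 0.7

    def test_linear_combination_removed_by_vif(self):
        # x3 = x1 + x2 + tiny noise; pairwise correlations stay moderate but
        # VIF = 1/(1-R^2) blows up
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=(2, 300))
        x3 = x1 + x2 + rng.normal(0, 0.01, 300)
        report = prune_collinear(env_of(np.column_stack([x1, x2, x3])))
        assert len(report.removed) == 1
        assert "VIF" in report.removed[0][1]
        assert (report.vif <= 10.0).all()

    def test_high_missingness_removed_first(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 3))
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df.loc[df.index[:60], "b"] = np.nan
        report = prune_collinear(EnvTable(df))
        assert report.removed[0][0] == "b"
        assert "missing" in report.removed[0][1]

    def test_retained_set_satisfies_both_cutoffs(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(150, 4))
        mixed = base @ rng.normal(size=(4, 8)) + rng.normal(0, 0.3, (150, 8))
        report = prune_collinear(env_of(np.hstack([base, mixed])))
        assert (report.vif <= 10.0).all()
        assert report.max_abs_corr <= 0.7


class TestEnvScreen:
    def test_planted_link_flagged(self, small_table):
        otu = small_table.counts.columns[0]
        env = simulate_env(small_table.n_samples, n_params=5,
                           linked_otus=[otu], link_r=0.9, seed=1,
                           table=small_table)
        clades = small_table.proportions
        results = env_screen(clades, env)
        flagged = {a.label for a in results if a.flag_passed}
        assert f"{otu}|param01_{otu}" in flagged

    def test_null_parameters_rarely_flagged(self, small_table):
        env = simulate_env(small_table.n_samples, n_params=10, seed=2)
        env.values.index = small_table.counts.index
        clades = collapse_rank(small_table, "genus")
        results = env_screen(clades, env)
        assert len(results) >= 100
        assert sum(a.flag_passed for a in results) <= 2

    def test_threshold_rule_blocks_weak_r(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=500)
        w = rng.normal(size=500)
        w -= z * (w @ z) / (z @ z)
        x = 0.29 * z + np.sqrt(1 - 0.29 ** 2) * (w / w.std())
        clades = pd.DataFrame({"c": z}, index=[f"s{i}" for i in range(500)])
        env = env_of(x[:, None], cols=["p"], index=clades.index)
        results = env_screen(clades, env, alpha=0.001, r_min=0.3)
        assert results[0].p_raw < 1e-6          # strongly significant ...
        assert not results[0].flag_passed        # ... but fails |r| > 0.3


class TestPhaseKw:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 10000
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(6)]
            h, p = stats.kruskal(*groups)
            rejections += p < 0.001
        assert rejections / reps < 0.004

    def test_shifted_group_detected_against_two_plus_others(self):
        rng = np.random.default_rng(8)
        phases = ["spring", "autumn", "winter", "epilimnion", "metalimnion",
                  "hypolimnion"]
        idx = [f"s{i}" for i in range(180)]
        lab = pd.Series([phases[i % 6] for i in range(180)], index=idx)
        vals = rng.normal(size=180)
        vals[np.array([i % 6 == 2 for i in range(180)])] += 5.0
        clades = pd.DataFrame({"c": vals}, index=idx)
        results = phase_kw(clades, lab, alpha=0.001)
        res = results[0]
        assert res.p_raw < 0.001
        assert "winter" in res.detail["phases_vs_two_plus"]

    def test_two_groups_reduce_to_rank_sum_test(self):
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(60)]
        lab = pd.Series(["a"] * 30 + ["b"] * 30, index=idx)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)])
        clades = pd.DataFrame({"c": vals}, index=idx)
        res = phase_kw(clades, lab, alpha=0.05)[0]
        ref = stats.mannwhitneyu(vals[:30], vals[30:], method="asymptotic",
                                 use_continuity=False)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-6)

    def test_single_group_rejected(self):
        idx = [f"s{i}" for i in range(10)]
        lab = pd.Series(["x"] * 10, index=idx)
        clades = pd.DataFrame({"c": np.arange(10.0)}, index=idx)
        with pytest.raises(InvalidArgumentError):
            phase_kw(clades, lab)


def cohort_net(weights):
    """Star network: target t linked to neighbors with given weights."""
    g = nx.Graph()
    for k, w in enumerate(weights):
        g.add_edge("t", f"n{k}", weight=float(w), sign=1 if w >= 0 else -1)
    net = ConsensusNetwork(g)
    cohort = Cohort(frozenset({"t"}),
                    {f"n{k}": (1 if w >= 0 else -1, float(w))
                     for k, w in enumerate(weights)}, name="test")
    return net, cohort


class TestPdVsCorrelation:
    def pd_matrix(self, dists):
        ids = ["t"] + [f"n{k}" for k in range(len(dists))]
        m = pd.DataFrame(0.0, index=ids, columns=ids)
        for k, dd in enumerate(dists):
            m.loc["t", f"n{k}"] = m.loc[f"n{k}", "t"] = dd
        return m

    def test_distance_decaying_weights_give_negative_r(self):
        rng = np.random.default_rng(10)
        dists = np.linspace(0.2, 2.0, 30)
        weights = 0.9 - 0.35 * dists + rng.normal(0, 0.05, 30)
        net, cohort = cohort_net(weights)
        res, scatter = pd_vs_correlation(cohort, net, self.pd_matrix(dists))
        assert len(scatter) == 30
        assert res.statistic < -0.5
        assert res.p_raw < 0.01

    def test_independent_weights_rarely_significant(self):
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            dists = rng.uniform(0.2, 2.0, 25)
            weights = rng.uniform(0.3, 0.9, 25)
            net, cohort = cohort_net(weights)
            res, _ = pd_vs_correlation(cohort, net, self.pd_matrix(dists))
            sig += res.p_raw < 0.05
        assert sig <= 2

    def test_single_pair_undefined(self):
        net, cohort = cohort_net([0.5])
        res, _ = pd_vs_correlation(cohort, net, self.pd_matrix([1.0]))
        assert np.isnan(res.statistic)
        assert "undefined" in res.detail


class TestCrossDatasetCorr:
    def test_identity_gives_unit_correlations(self, small_table):
        results = cross_dataset_corr(small_table, small_table)
        for a in results:
            if a.label.startswith("all|") and "vs_log_avra" in a.label:
                assert a.statistic == pytest.approx(1.0)
            if a.label == "all|prevalence_vs_prevalence":
                assert a.statistic == pytest.approx(1.0)

    def test_independent_tables_weakly_correlated(self):
        weak = 0
        for seed in range(20):
            tax = make_taxonomy(100, 5, seed=seed)
            ta = simulate_timeseries(tax, make_truth_network(tax, 0, seed=seed),
                                     40, depth=1500, seed=seed)
            tb = simulate_timeseries(tax,
                                     make_truth_network(tax, 0, seed=seed + 500),
                                     40, depth=1500, seed=seed + 500)
            res = {a.label: a for a in cross_dataset_corr(ta, tb)}
            weak += abs(res["all|prevalence_vs_prevalence"].statistic) < 0.3
        assert weak >= 18

    def test_culture_prevalence_tracks_lake_prevalence(self):
        # occupancy 1 - exp(-lambda f) is monotone in lake frequency, so
        # prevalence should correlate across datasets even without growth;
        # needs a community with real prevalence spread (many rare OTUs)
        tax = make_taxonomy(100, 5, seed=76)
        truth = make_truth_network(tax, 0, seed=76, base_sd=2.0)
        ts = simulate_timeseries(tax, truth, 60, depth=1500, seed=76)
        comp = ts.av_ra / ts.av_ra.sum()
        expt = simulate_cultures(tax, truth, comp, n_cultures=200, seed=77,
                                 culturable_mass_fraction=0.0)
        res = {a.label: a for a in cross_dataset_corr(ts, expt.table)}
        pearson_r = res["all|prevalence_vs_prevalence"].statistic
        assert pearson_r > 0.3
        assert res["all|prevalence_vs_prevalence"].p_adj < 0.01
        # the occupancy link is monotone but saturates on different scales
        # of lake frequency in the two designs, so the rank correlation is
        # the sharper statement of the link
        rho = stats.spearmanr(ts.prevalence, expt.table.prevalence).statistic
        assert rho > 0.5

    def test_requires_shared_otus(self, small_table):
        other = small_table.select_otus(small_table.counts.columns[:5])
        other.counts.columns = [f"zz{k}" for k in range(5)]
        other.taxonomy.index = other.counts.columns
        with pytest.raises(InvalidArgumentError):
            cross_dataset_corr(small_table, other)
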