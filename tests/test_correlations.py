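"""The four association estimators and their supporting transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cohortnet import (InvalidArgumentError, basis_correlations,
                       bh_adjust_matrix, clr_transform, dice_sorensen,
                       make_taxonomy, make_truth_network, mb_network,
                       pearson_matrix, simulate_timeseries, sparcc,
                       sparcc_pvalues)
from conftest import toy_table


class TestPearson:
    def test_duplicated_otu_perfectly_correlated(self):
        table = toy_table([[10, 10, 80], [20, 20, 60], [5, 5, 90], [30, 30, 40]])
        res = pearson_matrix(table)
        assert res.coef.iloc[0, 1] == pytest.approx(1.0)
        assert res.p_adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_proportions_give_minus_one(self):
        # proportions of o0 and o1 move exactly oppositely
        table = toy_table([[10, 30, 60], [20, 20, 60], [30, 10, 60]])
        res = pearson_matrix(table)
        assert res.coef.iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_otu_undefined_and_excluded(self):
        table = toy_table([[10, 50, 40], [20, 50, 30], [30, 50, 20]])
        res = pearson_matrix(table)
        # o1's proportion is constant -> its correlations are undefined
        assert np.isnan(res.coef.iloc[0, 1])
        assert np.isnan(res.p_adj.iloc[0, 1])
        assert not np.isnan(res.coef.iloc[0, 2])

    def test_needs_three_samples(self):
        with pytest.raises(InvalidArgumentError):
            pearson_matrix(toy_table([[1, 2], [3, 4]]))

    def test_padj_at_least_praw_and_monotone(self, small_table):
        res = pearson_matrix(small_table)
        iu, ju = np.triu_indices(small_table.n_otus, k=1)
        raw = res.p_raw.to_numpy()[iu, ju]
        adj = res.p_adj.to_numpy()[iu, ju]
        ok = ~np.isnan(raw)
        assert (adj[ok] >= raw[ok] - 1e-15).all()
        assert adj[ok].max() <= 1.0
        order = np.argsort(raw[ok])
        assert (np.diff(adj[ok][order]) >= -1e-12).all()


class TestBH:
    def test_step_up_on_three_pvalues(self):
        # direct evaluation of the step-up formula:
        # (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
        p = np.full((3, 3), np.nan)
        p[0, 1] = p[1, 0] = 0.01
        p[0, 2] = p[2, 0] = 0.02
        p[1, 2] = p[2, 1] = 0.04
        adj = bh_adjust_matrix(p)
        assert adj[0, 1] == pytest.approx(0.03, abs=1e-10)
        assert adj[0, 2] == pytest.approx(0.03, abs=1e-10)
        assert adj[1, 2] == pytest.approx(0.04, abs=1e-10)

    def test_by_variant_is_more_conservative(self):
        p = np.full((3, 3), np.nan)
        p[0, 1] = p[1, 0] = 0.01
        p[0, 2] = p[2, 0] = 0.02
        p[1, 2] = p[2, 1] = 0.04
        bh = bh_adjust_matrix(p, "fdr_bh")
        by = bh_adjust_matrix(p, "fdr_by")
        assert (by[0, 1] >= bh[0, 1]) and (by[1, 2] >= bh[1, 2])


class TestClr:
    def test_uniform_sample_maps_to_zero(self):
        out = clr_transform(np.array([[5, 5, 5, 5]]), pseudocount=0.5)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_computed_two_part_sample(self):
        # counts (1, 3), pseudocount 1: logs (log2, log4), centered ->
        # (-0.34657, +0.34657)
        out = clr_transform(np.array([[1, 3]]), pseudocount=1.0)
        np.testing.assert_allclose(out, [[-np.log(2) / 2, np.log(2) / 2]],
                                   atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.lists(st.integers(0, 1000), min_size=3, max_size=8),
                    min_size=1, max_size=5).filter(
                        lambda r: len({len(x) for x in r}) == 1))
    def test_rows_sum_to_zero(self, rows):
        out = clr_transform(np.array(rows), pseudocount=1.0)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(InvalidArgumentError):
            clr_transform(np.array([[1, 2]]), pseudocount=0.0)


class TestSparcc:
    def test_closed_form_three_component_system(self):
        # all log-ratio variances equal t0: basis variances solve to t0/2
        # and all basis correlations vanish
        t0 = 0.8
        T = np.full((3, 3), t0)
        np.fill_diagonal(T, 0.0)
        state = basis_correlations(T)
        np.testing.assert_allclose(state.omega, t0 / 2, atol=1e-8)
        off = state.rho[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-8)
        assert state.excluded_pairs == set()

    def test_planted_pair_recovered_against_independents(self):
        tax = make_taxonomy(52, 4, seed=20)
        truth = make_truth_network(tax, 0, seed=20, amplitude_max=1e-9)
        a, b = tax.otu_ids[0], tax.otu_ids[1]
        truth.edges.append((a, b, 1, 0.9))
        table = simulate_timeseries(tax, truth, 300, depth=1500, seed=20)
        res, _ = sparcc(table, seed=21)
        rho = res.coef
        assert rho.at[a, b] > 0.5
        others = rho.to_numpy()[np.triu_indices(52, k=1)]
        assert np.median(np.abs(others)) < 0.15

    def test_replicated_column_triggers_exclusion_loop(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(60, 6))
        counts[:, 1] = counts[:, 0]          # identical replicate
        table = toy_table(counts)
        _, state = sparcc(table, seed=3)
        assert (0, 1) in state.excluded_pairs
        assert state.iterations_used >= 1

    def test_shuffled_data_has_no_association(self, small_taxa, small_truth):
        table = simulate_timeseries(small_taxa, small_truth, 350, depth=1500,
                                    seed=70)
        rng = np.random.default_rng(7)
        counts = table.counts.to_numpy().copy()
        for k in range(counts.shape[1]):
            rng.shuffle(counts[:, k])
        res, _ = sparcc(toy_table(counts), seed=7)
        off = res.coef.to_numpy()[np.triu_indices(counts.shape[1], k=1)]
        assert np.median(np.abs(off)) < 0.05

    def test_symmetric_and_bounded(self, small_table):
        res, _ = sparcc(small_table, seed=5)
        rho = res.coef.to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        assert (np.abs(rho) <= 1.0 + 1e-12).all()

    def test_requires_four_otus(self):
        with pytest.raises(InvalidArgumentError):
            sparcc(toy_table([[1, 2, 3]] * 5), seed=1)


class TestSparccPvalues:
    def test_perfect_pair_attains_continuity_floor(self):
        rng = np.random.default_rng(11)
        base = rng.integers(10, 300, size=(40, 5))
        base[:, 1] = base[:, 0]
        table = toy_table(base)
        p_raw, _ = sparcc_pvalues(table, n_boot=100, seed=11, max_iter=20)
        assert p_raw.iloc[0, 1] == pytest.approx(1 / 101)

    def test_single_bootstrap_has_two_attainable_values(self):
        rng = np.random.default_rng(12)
        table = toy_table(rng.integers(1, 100, size=(30, 5)))
        p_raw, _ = sparcc_pvalues(table, n_boot=1, seed=12, max_iter=10)
        vals = np.unique(p_raw.to_numpy()[np.triu_indices(5, k=1)])
        assert set(np.round(vals, 12)) <= {0.5, 1.0}

    def test_independent_pairs_roughly_calibrated(self):
        # fraction of pseudo-p below 0.1 near 0.1 for independent OTUs
        tax = make_taxonomy(15, 3, seed=40)
        truth = make_truth_network(tax, 0, seed=41, amplitude_max=1e-9)
        table = simulate_timeseries(tax, truth, 200, depth=1500, seed=42)
        p_raw, _ = sparcc_pvalues(table, n_boot=100, seed=43)
        ps = p_raw.to_numpy()[np.triu_indices(15, k=1)][:100]
        assert (ps < 0.1).mean() == pytest.approx(0.1, abs=0.06)


class TestDice:
    def test_identical_disjoint_and_half(self):
        table = toy_table([[1, 1, 0, 2], [2, 3, 0, 0], [0, 0, 5, 1]])
        res = dice_sorensen(table)
        assert res.coef.iloc[0, 1] == pytest.approx(1.0)   # identical presence
        assert res.coef.iloc[0, 2] == pytest.approx(0.0)   # disjoint
        # |a|=2, |b|=2, |a&b|=1 -> 0.5
        assert res.coef.iloc[1, 3] == pytest.approx(0.5)

    def test_all_absent_otu_undefined(self):
        table = toy_table([[1, 0], [2, 0]])
        res = dice_sorensen(table)
        assert np.isnan(res.coef.iloc[0, 1])

    def test_bounds_and_identity_condition(self, small_table):
        res = dice_sorensen(small_table)
        coef = res.coef.to_numpy()
        iu, ju = np.triu_indices(small_table.n_otus, k=1)
        vals = coef[iu, ju]
        ok = ~np.isnan(vals)
        assert ((vals[ok] >= 0) & (vals[ok] <= 1)).all()
        pres = small_table.counts.to_numpy() > 0
        for a, b in zip(iu, ju):
            if not np.isnan(coef[a, b]) and coef[a, b] == 1.0:
                assert (pres[:, a] == pres[:, b]).all()


class TestMbNetwork:
    def test_lambda_path_has_requested_length(self, small_table):
        _, state = mb_network(small_table, n_reps=5, seed=1)
        assert len(state.lambda_path) == 20
        assert (np.diff(state.lambda_path) < 0).all()

    def test_selected_instability_within_beta(self, small_table):
        _, state = mb_network(small_table, n_reps=10, seed=2)
        assert state.monotone_instability[state.selected_index] <= state.beta

    def test_null_graph_is_sparse(self):
        tax = make_taxonomy(50, 4, seed=30)
        truth = make_truth_network(tax, 0, seed=30, amplitude_max=1e-9)
        table = simulate_timeseries(tax, truth, 300, depth=1500, seed=30)
        res, _ = mb_network(table, seed=30)
        density = res.support.to_numpy()[np.triu_indices(50, k=1)].mean()
        assert density < 0.02

    def test_chain_recovery_respects_conditional_independence(self):
        # Markov chain A -> B -> C in the latent log-abundances (A and C
        # conditionally independent given B): the direct links should be
        # found and the transitive A-C association rejected, in most
        # replicates.
        hits = 0
        n, d = 500, 25
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            latent = rng.normal(0, 0.8, size=(n, d))
            a_lat = rng.normal(0, 1.0, n)
            b_lat = 0.8 * a_lat + rng.normal(0, 0.6, n)
            c_lat = 0.8 * b_lat + rng.normal(0, 0.6, n)
            latent[:, 0], latent[:, 1], latent[:, 2] = a_lat, b_lat, c_lat
            p = np.exp(latent)
            p /= p.sum(axis=1, keepdims=True)
            counts = np.vstack([rng.multinomial(1500, p[s]) for s in range(n)])
            res, _ = mb_network(toy_table(counts), n_reps=20, seed=seed)
            sup = res.support.to_numpy()
            if sup[0, 1] and sup[1, 2] and not sup[0, 2]:
                hits += 1
        assert hits >= 16

    def test_support_symmetric_with_signs(self, small_table):
        res, _ = mb_network(small_table, n_reps=10, seed=4)
        sup = res.support.to_numpy()
        assert (sup == sup.T).all()
        sgn = res.sign.to_numpy()
        assert (sgn == sgn.T).all()
        assert set(np.unique(sgn)) <= {-1, 0, 1}
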