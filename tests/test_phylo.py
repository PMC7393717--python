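"""Tree utilities, independent contrasts, Mk likelihood, stochastic
character maps, and Brownian simulation."""

import numpy as np
import pytest

from conftest import newick_tree
from modulevo import phylo, synthgen
from modulevo.phylo import (MkModel, average_transitions, fit_mk2,
                            fitch_parsimony_length, gls_mean, inv_sqrt_psd,
                            is_ultrametric, make_ultrametric, mk2_loglik,
                            phylo_covariance, pic, prune_to, read_trees,
                            sim_bm_tips, simmap_sample, tip_labels,
                            write_trees, _pmat, _uniformization_path)


def pairwise_distances(tree, taxa):
    C, order = phylo_covariance(tree, taxa_order=taxa)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2 * C


class TestTreeIO:
    def test_round_trip_preserves_branch_lengths(self, tmp_path, small_tree):
        p = tmp_path / "t.nwk"
        write_trees(small_tree, p)
        back = read_trees(p)[0]
        C1, taxa = phylo_covariance(small_tree)
        C2, _ = phylo_covariance(back, taxa_order=taxa)
        assert np.allclose(C1, C2, atol=1e-12)

    def test_nexus_round_trip(self, tmp_path, small_tree):
        p = tmp_path / "t.nex"
        write_trees(small_tree, p, schema="nexus")
        back = read_trees(p)[0]
        assert sorted(tip_labels(back)) == sorted(tip_labels(small_tree))

    def test_prune_nothing_is_identity(self, small_tree):
        taxa = tip_labels(small_tree)
        pruned = prune_to(small_tree, taxa)
        assert np.allclose(pairwise_distances(small_tree, sorted(taxa)),
                           pairwise_distances(pruned, sorted(taxa)), atol=1e-12)

    def test_prune_three_tip_tree_preserves_depths(self):
        tree = newick_tree("((A:1,B:1):1,C:2);")
        pruned = prune_to(tree, ["A", "C"])
        assert sorted(tip_labels(pruned)) == ["A", "C"]
        depths = [lf.distance_from_root() for lf in pruned.leaf_node_iter()]
        assert np.allclose(sorted(depths), [2, 2])

    def test_prune_large_tree_distance_oracle(self):
        cfg = synthgen.SimulationConfig(seed=9, n_otus=40, n_trees=1)
        tree = synthgen.simulate_tree(cfg)
        all_taxa = sorted(tip_labels(tree))
        survivors = all_taxa[:22]
        idx = [all_taxa.index(t) for t in survivors]
        before = pairwise_distances(tree, all_taxa)[np.ix_(idx, idx)]
        pruned = prune_to(tree, survivors)
        assert len(tip_labels(pruned)) == 22
        assert np.allclose(before, pairwise_distances(pruned, survivors),
                           atol=1e-10)

    def test_prune_missing_taxa_listed(self, small_tree):
        with pytest.raises(ValueError, match="nosuch"):
            prune_to(small_tree, ["nosuch", tip_labels(small_tree)[0]])

    def test_make_ultrametric_refuses_without_flag(self):
        tree = newick_tree("((A:1,B:2):1,C:4);")
        with pytest.raises(ValueError, match="approximate"):
            make_ultrametric(tree)
        fixed = make_ultrametric(tree, approximate=True)
        assert is_ultrametric(fixed, rtol=1e-9)


class TestPIC:
    def test_two_tip_closed_form(self):
        tree = newick_tree("(A:1,B:1);")
        cs = pic(tree, np.array([[0.0], [2.0]]), labels=["A", "B"])
        assert cs.contrasts.shape == (1, 1)
        assert abs(abs(cs.contrasts[0, 0]) - np.sqrt(2)) < 1e-12

    def test_contrast_count_identity(self, small_tree, rng):
        n = len(tip_labels(small_tree))
        X = rng.normal(size=(n, 3))
        cs = pic(small_tree, X, labels=sorted(tip_labels(small_tree)))
        assert cs.contrasts.shape == (n - 1, 3)

    def test_contrast_correlation_equals_gls_oracle(self):
        """The cross-trait correlation of contrasts equals the GLS correlation
        computed directly from C^-1 (checked on 8-tip trees)."""
        for seed in range(5):
            cfg = synthgen.SimulationConfig(seed=seed, n_otus=8, n_trees=1)
            tree = synthgen.simulate_tree(cfg)
            taxa = sorted(tip_labels(tree))
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(8, 2))
            cs = pic(tree, X, labels=taxa)
            u, v = cs.contrasts[:, 0], cs.contrasts[:, 1]
            r_pic = (u @ v) / np.sqrt((u @ u) * (v @ v))
            C, _ = phylo_covariance(tree, taxa_order=taxa)
            Ci = np.linalg.inv(C)
            one = np.ones(8)
            a = (one @ Ci @ X) / (one @ Ci @ one)
            E = X - a
            S = E.T @ Ci @ E
            r_gls = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
            assert abs(r_pic - r_gls) < 1e-10

    def test_pic_variance_matches_gls_estimator(self):
        cfg = synthgen.SimulationConfig(seed=4, n_otus=7, n_trees=1)
        tree = synthgen.simulate_tree(cfg)
        taxa = sorted(tip_labels(tree))
        x = np.random.default_rng(4).normal(size=(7, 1))
        cs = pic(tree, x, labels=taxa)
        v_pic = (cs.contrasts ** 2).sum() / (7 - 1)
        C, _ = phylo_covariance(tree, taxa_order=taxa)
        Ci = np.linalg.inv(C)
        one = np.ones(7)
        a = (one @ Ci @ x) / (one @ Ci @ one)
        e = (x - a).ravel()
        v_gls = (e @ Ci @ e) / (7 - 1)
        assert abs(v_pic - v_gls) < 1e-10


class TestPhyloCovariance:
    def test_star_tree_identity(self):
        tree = newick_tree("(A:1,B:1,C:1,D:1);")
        C, _ = phylo_covariance(tree, taxa_order=list("ABCD"))
        assert np.allclose(C, np.eye(4), atol=1e-12)

    def test_two_tip_tree(self):
        tree = newick_tree("(A:2.5,B:2.5);")
        C, _ = phylo_covariance(tree, taxa_order=["A", "B"])
        assert np.allclose(C, 2.5 * np.eye(2), atol=1e-12)

    def test_gls_mean_matches_dense_oracle(self):
        cfg = synthgen.SimulationConfig(seed=2, n_otus=6, n_trees=1)
        tree = synthgen.simulate_tree(cfg)
        taxa = sorted(tip_labels(tree))
        C, _ = phylo_covariance(tree, taxa_order=taxa)
        Y = np.random.default_rng(2).normal(size=(6, 3))
        a = gls_mean(C, Y)
        Ci = np.linalg.inv(C)
        one = np.ones(6)
        expect = (one @ Ci @ Y) / (one @ Ci @ one)
        assert np.allclose(a, expect, atol=1e-10)

    def test_inv_sqrt(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        W = inv_sqrt_psd(C)
        assert np.allclose(W @ C @ W, np.eye(2), atol=1e-12)


class TestMk:
    def test_monomorphic_rate_at_lower_bound(self, small_tree):
        tips = {lab: "shallow" for lab in tip_labels(small_tree)}
        with pytest.warns(UserWarning, match="monomorphic"):
            model = fit_mk2(small_tree, tips)
        assert model.rate_sd <= 1e-7

    def test_three_tip_likelihood_exhaustive_oracle(self):
        """Pruning likelihood equals the explicit sum over the 4 internal x
        root state combinations on a 3-tip tree."""
        tree = newick_tree("((A:0.5,B:0.7):0.4,C:1.2);")
        tips = {"A": 0, "B": 1, "C": 0}
        a, b = 0.6, 0.9
        P = lambda t: _pmat(a, b, t)
        prior = MkModel(a, b).root_probs()
        total = 0.0
        for root in (0, 1):
            for internal in (0, 1):
                total += (prior[root]
                          * P(0.4)[root, internal]
                          * P(0.5)[internal, tips["A"]]
                          * P(0.7)[internal, tips["B"]]
                          * P(1.2)[root, tips["C"]])
        assert abs(mk2_loglik(tree, tips, a, b) - np.log(total)) < 1e-12

    def test_er_rate_recovery(self):
        """Median ML rate over replicates of q=0.5 data on 200-tip trees
        falls inside [0.35, 0.65]."""
        qhats = []
        for seed in range(50):
            cfg = synthgen.SimulationConfig(seed=seed, n_otus=200, n_trees=1,
                                            mk_rates=(0.5, 0.5))
            tree = synthgen.simulate_tree(cfg)
            tips, _ = synthgen.simulate_habitat(tree, cfg)
            if len(set(tips.values())) == 1:
                continue
            qhats.append(fit_mk2(tree, tips).rate_sd)
        assert 0.35 <= np.median(qhats) <= 0.65

    def test_ard_fits_two_rates(self, small_tree, small_config):
        tips, _ = synthgen.simulate_habitat(small_tree, small_config)
        if len(set(tips.values())) == 1:
            pytest.skip("monomorphic draw")
        m = fit_mk2(small_tree, tips, structure="ARD")
        assert m.structure == "ARD"
        er = fit_mk2(small_tree, tips, structure="ER")
        assert m.log_likelihood >= er.log_likelihood - 1e-6


class TestSimmap:
    def test_frozen_chain_zero_transitions(self, small_tree):
        tips = {lab: "shallow" for lab in tip_labels(small_tree)}
        model = MkModel(1e-9, 1e-9)
        for hist in simmap_sample(small_tree, tips, model, n_maps=10, seed=0):
            assert hist.n_transitions == 0
            assert set(hist.tip_states().values()) == {0}

    def test_maps_respect_parsimony_bound_and_tips(self, small_config):
        for seed in range(5):
            cfg = synthgen.SimulationConfig(**{**small_config.__dict__,
                                               "seed": seed})
            tree = synthgen.simulate_tree(cfg)
            tips, _ = synthgen.simulate_habitat(tree, cfg)
            if len(set(tips.values())) == 1:
                continue
            model = fit_mk2(tree, tips)
            bound = fitch_parsimony_length(tree, tips)
            idx = {k: 0 if v == "shallow" else 1 for k, v in tips.items()}
            for hist in simmap_sample(tree, tips, model, n_maps=20, seed=seed):
                assert hist.n_transitions >= bound
                assert hist.tip_states() == idx

    def test_branch_path_matches_independent_rejection_oracle(self, rng):
        """Mean event count of the package's endpoint-conditioned sampler
        (uniformization) matches a test-local rejection sampler within 3 SE."""
        a, b, t = 0.9, 1.4, 1.3
        for (i, j) in [(0, 0), (0, 1), (1, 0)]:
            n_pkg = [len(_uniformization_path(i, j, t, a, b, rng))
                     for _ in range(10_000)]
            # independent oracle: naive forward simulation + rejection
            oracle = []
            rates = (a, b)
            while len(oracle) < 4000:
                events = 0
                state, now = i, 0.0
                while True:
                    now += rng.exponential(1.0 / rates[state])
                    if now >= t:
                        break
                    state = 1 - state
                    events += 1
                if state == j:
                    oracle.append(events)
            se = np.sqrt(np.var(oracle) / len(oracle)
                         + np.var(n_pkg) / len(n_pkg))
            assert abs(np.mean(n_pkg) - np.mean(oracle)) < 3 * se + 1e-9

    def test_node_marginals_match_independent_reconstruction(self):
        """SIMMAP node-state frequencies over many maps converge to marginal
        ancestral reconstructions computed by brute-force state enumeration."""
        tree = newick_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")
        tips = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0, "F": 1}
        model = MkModel(0.4, 0.6)
        tt = phylo.tree_table(tree)
        maps = simmap_sample(tt, tips, model, n_maps=2000, seed=7)
        internal = [i for i in range(tt.n_nodes) if tt.children[i]]
        # brute force: enumerate all internal-state combinations
        from itertools import product
        leaf_map = dict(zip(tt.leaf_ids.tolist(), tt.leaf_labels))
        prior = model.root_probs()
        marg = {i: 0.0 for i in internal}
        total = 0.0
        for combo in product((0, 1), repeat=len(internal)):
            state = {}
            for i, s in zip(internal, combo):
                state[i] = s
            for i in tt.leaf_ids:
                state[int(i)] = tips[leaf_map[int(i)]]
            pr = prior[state[tt.root]]
            for i in range(tt.n_nodes):
                if i == tt.root:
                    continue
                par = tt.parent[i]
                pr *= _pmat(model.rate_sd, model.rate_ds,
                            tt.edge_length[i])[state[par], state[i]]
            total += pr
            for i in internal:
                marg[i] += pr * state[i]
        marg = {i: v / total for i, v in marg.items()}
        # frequency of state 1 at each internal node across sampled maps
        for i in internal:
            if i == tt.root:
                freq = np.mean([m.segments[tt.children[i][0]][0][2]
                                for m in maps])
            else:
                freq = np.mean([m.segments[i][-1][2] for m in maps])
            assert abs(freq - marg[i]) < 0.05

    def test_average_transitions_additivity_and_frozen(self, small_tree):
        tips = {lab: "shallow" for lab in tip_labels(small_tree)}
        with pytest.warns(UserWarning):
            s = average_transitions([small_tree] * 3, tips, seed=0)
        assert (s["mean_total"], s["mean_shallow_to_deep"],
                s["mean_deep_to_shallow"]) == (0.0, 0.0, 0.0)

    def test_directional_counts_sum_to_total(self, small_config):
        tree = synthgen.simulate_tree(small_config)
        tips, _ = synthgen.simulate_habitat(tree, small_config)
        trees = synthgen.simulate_tree_sample(
            tree, synthgen.SimulationConfig(**{**small_config.__dict__,
                                               "n_trees": 4}))
        s = average_transitions(trees, tips, seed=1)
        assert abs(s["mean_total"] - (s["mean_shallow_to_deep"]
                                      + s["mean_deep_to_shallow"])) < 1e-12

    def test_simmap_newick_annotates_branches(self, small_tree, small_config):
        tips, _ = synthgen.simulate_habitat(small_tree, small_config)
        model = fit_mk2(small_tree, tips)
        hist = simmap_sample(small_tree, tips, model, seed=0)[0]
        s = phylo.simmap_newick(small_tree, hist)
        assert s.endswith(";") and "{" in s and "shallow" in s or "deep" in s


class TestBrownianSim:
    def test_zero_rate_returns_root(self, small_tree):
        X = sim_bm_tips(small_tree, np.zeros((3, 3)), n_sims=2, seed=0,
                        root=np.array([1.0, 2.0, 3.0]))
        assert np.allclose(X, np.array([1.0, 2.0, 3.0]))

    def test_two_tip_covariance_moment_check(self):
        tree = newick_tree("(A:1,B:1);")
        R = np.array([[1.0, 0.5], [0.5, 2.0]])
        X = sim_bm_tips(tree, R, n_sims=5000, seed=3, taxa_order=["A", "B"])
        flat = X.reshape(5000, -1)        # (A_t1, A_t2, B_t1, B_t2)
        emp = np.cov(flat.T)
        expect = np.kron(np.eye(2), R)
        assert np.abs(emp - expect).max() < 0.05 * np.abs(expect).max() + 0.05

    def test_contrasts_of_bm_data_uncorrelated(self, small_tree):
        taxa = sorted(tip_labels(small_tree))
        X = sim_bm_tips(small_tree, np.eye(1), n_sims=1000, seed=5,
                        taxa_order=taxa)
        cons = np.stack([pic(small_tree, X[s], labels=taxa).contrasts[:, 0]
                         for s in range(1000)])
        corr = np.corrcoef(cons.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_dimension_mismatch_rejected(self, small_tree):
        with pytest.raises(ValueError):
            sim_bm_tips(small_tree, np.array([[1.0, 0.2]]), n_sims=1)
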