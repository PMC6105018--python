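"""Likelihood-engine tests: pruning vs exhaustive summation, conservation,
branch-length and site-rate recovery."""

import itertools

import numpy as np
import pytest

from radsignal import likelihood as lk
from radsignal import phylo_core as pc

from conftest import random_binary_tree, simulate_on_tree


def brute_force_site_likelihood(tree, pattern, model):
    """Exhaustive summation over all internal-node state assignments,
    including the rate-category mixture — the oracle for pruning."""
    k = model.n_states
    rates, weights = model.rate_categories()
    pi = model.equilibrium_frequencies
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    total = 0.0
    for rate, w in zip(rates, weights):
        Ps = {id(nd): model.transition_matrices(
            np.array([(nd.edge.length or 0.0) * rate]))[0]
            for nd in nodes if nd.parent_node is not None}
        lik = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            states = {id(nd): s for nd, s in zip(internals, assign)}
            for leaf in leaves:
                states[id(leaf)] = pattern[leaf.taxon.label]
            p = pi[states[id(tree.seed_node)]]
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                p *= Ps[id(nd)][states[id(nd.parent_node)], states[id(nd)]]
            lik += p
        total += w * lik
    return np.log(total)


class TestModels:
    def test_rate_matrix_normalized(self):
        for model in (lk.SubstitutionModel.jc(),
                      lk.SubstitutionModel.hky(4.0, [0.3, 0.2, 0.1, 0.4]),
                      lk.SubstitutionModel.mk(3)):
            Q = model.rate_matrix()
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            mu = -(model.equilibrium_frequencies * np.diag(Q)).sum()
            assert mu == pytest.approx(1.0)

    def test_gamma_categories_mean_one(self):
        for alpha in (0.2, 0.8, 2.0, 10.0):
            rates = lk.discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_stationarity(self):
        model = lk.SubstitutionModel.hky(3.0, [0.35, 0.15, 0.2, 0.3])
        P = model.transition_matrices(np.array([50.0]))[0]
        assert np.allclose(P, np.tile(model.equilibrium_frequencies, (4, 1)),
                           atol=1e-9)


class TestPruning:
    def test_identical_sequences_zero_branches(self):
        aln = pc.Alignment.from_dict({"A": "ACGT", "B": "ACGT"})
        tree = pc.parse_tree("(A:1e-9,B:1e-9);")
        got = lk.site_log_likelihoods(aln, tree, lk.SubstitutionModel.jc())
        assert np.allclose(got.log_likelihoods, np.log(0.25), atol=1e-6)

    def test_independence_limit(self):
        aln = pc.Alignment.from_dict({"A": "ACGT", "B": "TGCA"})
        tree = pc.parse_tree("(A:19,B:19);")
        got = lk.site_log_likelihoods(aln, tree, lk.SubstitutionModel.jc())
        assert np.allclose(got.log_likelihoods, np.log(1.0 / 16), atol=1e-6)

    @pytest.mark.parametrize("model", [
        lk.SubstitutionModel.jc(),
        lk.SubstitutionModel.hky(3.5, [0.35, 0.15, 0.2, 0.3],
                                 gamma_shape=0.7),
        lk.SubstitutionModel.gtr([1.2, 3.0, 0.6, 1.1, 4.0, 1.0],
                                 [0.3, 0.25, 0.2, 0.25], gamma_shape=1.2,
                                 prop_invariant=0.15),
    ])
    def test_matches_exhaustive_enumeration(self, model, rng):
        """Pruning equals brute-force summation over internal states on
        random trees with up to 5 leaves."""
        for n_leaves in (3, 4, 5):
            tree = random_binary_tree(list("ABCDE")[:n_leaves], rng)
            aln = simulate_on_tree(tree, 3, model, rng)
            got = lk.site_log_likelihoods(aln, tree, model).log_likelihoods
            for j in range(3):
                pattern = {t: model.states.index(aln.sequence(t)[j])
                           for t in aln.taxa}
                expect = brute_force_site_likelihood(tree, pattern, model)
                assert got[j] == pytest.approx(expect, abs=1e-10)

    def test_pattern_probability_conservation(self, rng):
        """Sum of pattern probabilities over all 4^n site patterns is 1."""
        model = lk.SubstitutionModel.hky(2.5, [0.3, 0.2, 0.2, 0.3],
                                         gamma_shape=0.9)
        tree = random_binary_tree(list("ABCD"), rng)
        total = 0.0
        for pat in itertools.product("ACGT", repeat=4):
            aln = pc.Alignment.from_dict(dict(zip("ABCD", pat)))
            total += np.exp(lk.site_log_likelihoods(aln, tree, model)
                            .log_likelihoods[0])
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_gamma_limit_single_rate(self, rng):
        """alpha -> infinity collapses the gamma mixture to one rate."""
        tree = random_binary_tree(list("ABCDE"), rng)
        aln = simulate_on_tree(tree, 50, lk.SubstitutionModel.jc(), rng)
        l_single = lk.site_log_likelihoods(
            aln, tree, lk.SubstitutionModel.jc()).log_likelihoods
        l_gamma = lk.site_log_likelihoods(
            aln, tree, lk.SubstitutionModel.jc(gamma_shape=1e6)
        ).log_likelihoods
        assert np.max(np.abs((l_gamma - l_single) / l_single)) < 1e-4

    def test_ambiguity_codes_never_minus_inf(self):
        aln = pc.Alignment.from_dict({"A": "RYN-", "B": "ACG?", "C": "WSKT"})
        tree = pc.parse_tree("((A:0.1,B:0.1):0.1,C:0.1);")
        got = lk.site_log_likelihoods(aln, tree, lk.SubstitutionModel.jc())
        assert np.isfinite(got.log_likelihoods).all()


class TestBranchOptimization:
    def test_monotone_improvement(self, rng):
        tree = random_binary_tree(list("ABCDEF"), rng)
        model = lk.SubstitutionModel.jc()
        aln = simulate_on_tree(tree, 200, model, rng)
        before = lk.total_log_likelihood(aln, tree, model)
        _, after = lk.optimize_branch_lengths(aln, tree, model, max_rounds=3)
        assert after >= before

    def test_identical_sequences_hit_lower_bound(self):
        aln = pc.Alignment.from_dict({t: "ACGTACGT" for t in "ABC"})
        tree = pc.parse_tree("((A:0.1,B:0.1):0.1,C:0.1);")
        opt, _ = lk.optimize_branch_lengths(aln, tree,
                                            lk.SubstitutionModel.jc())
        for nd in opt.preorder_node_iter():
            if nd.edge.length is not None and nd is not opt.seed_node:
                assert nd.edge.length < 1e-4

    def test_simulation_recovery_within_15_percent(self, rng):
        true = pc.parse_tree(
            "((A:0.12,B:0.2):0.06,(C:0.15,D:0.09):0.08,E:0.25);")
        model = lk.SubstitutionModel.jc()
        aln = simulate_on_tree(true, 5000, model, rng)
        opt, _ = lk.optimize_branch_lengths(aln, true, model)
        for nd_true, nd_est in zip(true.preorder_node_iter(),
                                   opt.preorder_node_iter()):
            if nd_true.edge.length is None or nd_true is true.seed_node:
                continue
            assert nd_est.edge.length == pytest.approx(
                nd_true.edge.length, rel=0.15)


class TestPerSiteRates:
    def test_constant_columns_rate_zero(self):
        aln = pc.Alignment.from_dict({"A": "AAAA", "B": "AAAA", "C": "AAAA",
                                      "D": "AAAA"})
        chrono = pc.parse_tree("((A:50,B:50):50,(C:50,D:50):50);")
        srv = lk.per_site_rates(aln, chrono)
        assert (srv.rates == 0.0).all()

    def _balanced_chronogram(self, n, depth):
        def bal(labels, d):
            if len(labels) == 1:
                return f"{labels[0]}:{d}"
            h = len(labels) // 2
            return f"({bal(labels[:h], d / 2)},{bal(labels[h:], d / 2)}):{d / 2}"
        labs = [f"T{i}" for i in range(n)]
        return pc.parse_tree(
            f"({bal(labs[:n // 2], depth)},{bal(labs[n // 2:], depth)});")

    def test_two_rate_classes_ratio_near_two(self, rng):
        """Columns simulated at rate 2r vs r recover a mean-rate ratio
        within 10% of 2 (replicate columns averaged)."""
        chrono = self._balanced_chronogram(16, 100.0)
        model = lk.SubstitutionModel.jc()
        mats = []
        for r in (0.002, 0.004):
            scaled = chrono.clone(depth=1)
            for nd in scaled.preorder_node_iter():
                if nd.edge.length:
                    nd.edge.length *= r
            mats.append(simulate_on_tree(scaled, 500, model, rng).matrix)
        taxa = [f"T{i}" for i in range(16)]
        aln = pc.Alignment(taxa, np.hstack(mats))
        srv = lk.per_site_rates(aln, chrono, model)
        ratio = srv.rates[500:].mean() / srv.rates[:500].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_rescaling_identity(self, rng):
        """Doubling chronogram depths halves the per-unit-time rates."""
        chrono = self._balanced_chronogram(8, 100.0)
        scaled = chrono.clone(depth=1)
        for nd in scaled.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= 2.0
        sim_tree = chrono.clone(depth=1)
        for nd in sim_tree.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= 0.003
        model = lk.SubstitutionModel.jc()
        aln = simulate_on_tree(sim_tree, 300, model, rng)
        r1 = lk.per_site_rates(aln, chrono, model).rates
        r2 = lk.per_site_rates(aln, scaled, model).rates
        ok = r1 > 1e-6
        assert np.allclose(r2[ok] / r1[ok], 0.5, rtol=1e-3)


class TestClassSearch:
    def test_single_topology_class(self, rng):
        from radsignal import backbone_space as bs
        bb = bs.BackboneTopology((("W", "X"), ("Y", "Z")))
        subtrees = {c: f"({c}a:0.05,{c}b:0.05):0.05" for c in "WXYZ"}
        model = lk.SubstitutionModel.jc()
        tree = lk.graft_backbone(bb, subtrees)
        aln = simulate_on_tree(tree, 300, model, rng)
        best, ll = lk.best_tree_in_class(aln, [bb], subtrees, model,
                                         screen_top=1)
        assert pc.nontrivial_splits(best) >= {frozenset({"Ya", "Yb", "Za", "Zb"})}
        with pytest.raises(ValueError):
            lk.best_tree_in_class(aln, [], subtrees, model)

    def test_true_class_wins(self, rng):
        """Data simulated on a backbone in class A gives class A the
        highest class-maximum likelihood."""
        from radsignal import backbone_space as bs
        labels = ["W", "X", "Y", "Z"]
        subtrees = {c: f"({c}a:0.05,{c}b:0.05):0.05" for c in labels}
        true_bb = bs.BackboneTopology((("W", "X"), ("Y", "Z")))
        model = lk.SubstitutionModel.jc()
        true_tree = lk.graft_backbone(true_bb, subtrees,
                                      outgroup_newick="OG:0.3")
        aln = simulate_on_tree(true_tree, 1500, model, rng)
        hyps = {"A": frozenset({"W", "X"}), "B": frozenset({"Y", "W"})}
        classes = bs.backbones_by_class(labels, hyps)
        lls = {}
        for cls, bbs_ in classes.items():
            _, lls[cls] = lk.best_tree_in_class(
                aln, bbs_, subtrees, model, outgroup_newick="OG:0.3",
                screen_top=1)
        assert lls["A"] == max(lls.values())


class TestModelSelection:
    def test_bic_prefers_richer_model_on_biased_data(self, rng):
        model = lk.SubstitutionModel.hky(8.0, [0.4, 0.1, 0.1, 0.4],
                                         gamma_shape=0.8)
        tree = pc.parse_tree("((A:0.2,B:0.3):0.1,(C:0.25,D:0.2):0.1);")
        aln = simulate_on_tree(tree, 800, model, rng)
        name, chosen, bic = lk.select_model(aln, tree)
        assert not name.startswith("JC")
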