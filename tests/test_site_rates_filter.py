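"""OV / TIGER scoring, ranked removal, and NJ consistency tests."""

import numpy as np
import pytest

from radsignal import phylo_core as pc
from radsignal import site_rates_filter as srf
from radsignal.likelihood import SubstitutionModel

from conftest import random_binary_tree, simulate_on_tree


class TestOV:
    def test_examples(self):
        aln = pc.Alignment.from_dict({"t1": "AAA", "t2": "ACA",
                                      "t3": "AGC", "t4": "ATC"})
        # columns: AAAA -> 0; ACGT -> 1; AACC -> 4/6
        got = srf.ov_scores(aln)
        assert got[0] == 0.0
        assert got[1] == 1.0
        assert got[2] == pytest.approx(4 / 6)

    def test_missing_data_excluded(self):
        aln = pc.Alignment.from_dict({"a": "A-", "b": "A?", "c": "CN"})
        got = srf.ov_scores(aln)
        assert got[0] == pytest.approx(2 / 3)  # pairs AA, AC, AC
        assert np.isnan(got[1])  # fewer than two observed states

    def test_invariance_to_taxon_order_and_relabeling(self, rng):
        aln = pc.Alignment.from_dict({"a": "ACGTT", "b": "AGGAT",
                                      "c": "CCGTA", "d": "ACTTA"})
        base = srf.ov_scores(aln)
        shuffled = aln.subset_taxa(["c", "a", "d", "b"])
        assert np.allclose(srf.ov_scores(shuffled), base)
        relabeled = pc.Alignment(
            aln.taxa,
            np.vectorize({"A": "T", "C": "G", "G": "C", "T": "A"}.get)(
                aln.matrix))
        assert np.allclose(srf.ov_scores(relabeled), base)


class TestTiger:
    def test_identical_sites_score_one(self):
        aln = pc.Alignment.from_dict({"a": "AA", "b": "AA", "c": "CC",
                                      "d": "CC"})
        assert np.allclose(srf.tiger_scores(aln), 1.0)

    def test_constant_site_agreement(self):
        """Every state set nests inside a constant site's all-taxa set."""
        aln = pc.Alignment.from_dict({"a": "AA", "b": "AC", "c": "AG",
                                      "d": "AT"})
        scores = srf.tiger_scores(aln)
        assert scores[0] == 1.0  # pa(site2 -> constant site1) = 1

    def test_hand_enumerated_toy(self):
        """4-taxon, 3-site toy checked against exhaustive subset counts."""
        aln = pc.Alignment.from_dict({"t1": "AAA", "t2": "ABA",
                                      "t3": "BAA", "t4": "BBB"},
                                     alphabet="AB")
        # site1 sets {12},{34}; site2 {13},{24}; site3 {123},{4}
        # pa(2->1)=0, pa(3->1)=1/2; pa(1->2)=0, pa(3->2)=1/2
        # pa(1->3): {12} in {123}, {34} not -> 1/2 ; pa(2->3): {13} in, {24} not -> 1/2
        got = srf.tiger_scores(aln)
        assert got[0] == pytest.approx(0.25)
        assert got[1] == pytest.approx(0.25)
        assert got[2] == pytest.approx(0.5)

    def test_single_site_error(self):
        with pytest.raises(ValueError):
            srf.tiger_scores(pc.Alignment.from_dict({"a": "A", "b": "C"}))

    def test_scores_in_unit_interval_and_duplicate_no_decrease(self, rng):
        model = SubstitutionModel.jc()
        tree = random_binary_tree(list("ABCDEFGH"), rng)
        aln = simulate_on_tree(tree, 40, model, rng)
        scores = srf.tiger_scores(aln)
        assert ((scores >= 0) & (scores <= 1)).all()
        i = 5
        dup = pc.Alignment(
            aln.taxa, np.hstack([aln.matrix, aln.matrix[:, [i]]]))
        scores_dup = srf.tiger_scores(dup)
        assert scores_dup[i] >= scores[i] - 1e-12


class TestRanking:
    def test_tie_break_by_site_index(self):
        scores = np.array([0.5, 0.9, 0.5, 0.1])
        order = srf.rank_fastest_first(scores, higher_is_faster=True)
        assert list(order) == [1, 0, 2, 3]

    def test_rank_vs_truth(self, rng):
        true = np.arange(100, dtype=float)
        assert srf.rank_vs_truth(true.copy(), true) == pytest.approx(1.0)
        random_scores = rng.permutation(100).astype(float)
        assert abs(srf.rank_vs_truth(random_scores, true)) < 2 / np.sqrt(99) * 2

    def test_ov_correlates_with_gamma_rates(self, rng):
        """OV recovers the ordering of gamma-distributed site rates."""
        taxa = [f"T{i}" for i in range(20)]
        tree = random_binary_tree(taxa, rng)
        model = SubstitutionModel.jc()
        rates = rng.gamma(0.8, 1.25, size=200)
        mats = []
        for r in rates:  # one column per true rate
            scaled = tree.clone(depth=1)
            for nd in scaled.preorder_node_iter():
                if nd.edge.length:
                    nd.edge.length *= r
            col = simulate_on_tree(scaled, 1, model, rng)
            mats.append(col.subset_taxa(taxa).matrix)
        aln = pc.Alignment(taxa, np.hstack(mats))
        rho = srf.rank_vs_truth(srf.ov_scores(aln), rates)
        assert rho > 0.5


class TestDistancesAndNJ:
    def test_jc_distance_formula(self):
        aln = pc.Alignment.from_dict({"a": "A" * 80 + "C" * 20,
                                      "b": "A" * 100})
        D = srf.jc_distance_matrix(aln)
        p = 0.2
        expect = -0.75 * np.log(1 - 4 * p / 3)
        assert D[0, 1] == pytest.approx(expect)

    def test_nj_consistency_on_additive_distances(self, rng):
        """NJ reconstructs the generating topology exactly from additive
        (true path-length) distances — the classic consistency check."""
        for _ in range(10):
            tree = random_binary_tree(list("ABCDEFGH"), rng)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(t.label for t in tree.taxon_namespace)
            lab = {t.label: t for t in tree.taxon_namespace}
            D = np.array([[0.0 if a == b else
                           pdm.patristic_distance(lab[a], lab[b])
                           for b in taxa] for a in taxa])
            nj = srf.nj_from_distances(D, taxa)
            assert pc.rf_distance(nj, tree) == 0.0

    def test_ml_distance_tracks_truth_under_rate_variation(self, rng):
        """Mixture-aware ML distances recover the true separation when
        sites evolve at discrete-gamma rates (where raw JC saturates)."""
        from radsignal.likelihood import discrete_gamma_rates

        model = SubstitutionModel.jc(gamma_shape=0.8)
        mats = []
        for r in discrete_gamma_rates(0.8, 4):
            tree = pc.parse_tree(f"(a:{0.3 * r},b:{0.3 * r});")
            mats.append(simulate_on_tree(tree, 1500,
                                         SubstitutionModel.jc(), rng))
        aln = pc.Alignment(["a", "b"],
                           np.hstack([m.subset_taxa(["a", "b"]).matrix
                                      for m in mats]))
        D = srf.ml_distance_matrix(aln, model)
        assert D[0, 1] == pytest.approx(0.6, rel=0.15)


class TestRemovalSeries:
    def _setup(self, rng, n_clean=300, n_noise=300):
        """Clean signal for the reference topology in most sites, plus a
        fast-evolving minority carrying conflicting signal."""
        taxa = [f"T{i}" for i in range(12)]
        tree = random_binary_tree(taxa, rng)
        model = SubstitutionModel.jc()
        clean = simulate_on_tree(tree, n_clean, model, rng)
        other = random_binary_tree(taxa, rng)
        for nd in other.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length = nd.edge.length * 8 + 0.5
        noisy = simulate_on_tree(other, n_noise, model, rng)
        aln = pc.Alignment(clean.taxa,
                           np.hstack([clean.matrix,
                                      noisy.subset_taxa(clean.taxa).matrix]))
        return tree, aln

    def test_step_zero_reproduces_full_tree(self, rng):
        tree, aln = self._setup(rng)
        ranking = srf.rank_fastest_first(srf.ov_scores(aln), True)
        series = srf.removal_series(aln, ranking, tree, step=aln.n_sites)
        full_tree = srf.nj_tree(aln)
        assert pc.rf_distance(series.steps[0].tree, full_tree) == 0.0

    def test_step_larger_than_alignment_errors(self, rng):
        tree, aln = self._setup(rng)
        ranking = np.arange(aln.n_sites)
        with pytest.raises(ValueError):
            srf.removal_series(aln, ranking, tree, step=aln.n_sites + 1)
        with pytest.raises(ValueError):
            srf.removal_series(aln, ranking[:-1], tree, step=10)

    def test_ov_ranked_removal_preserves_backbone_longer(self, rng):
        """Stripping OV-fastest sites retains more reference splits than
        random removal while the noisy minority is being purged
        (median over seeds)."""
        def persistence(series, kmax=4):
            return sum(sum(st.split_presence.values())
                       for st in series.steps[:kmax])

        wins = []
        for seed in range(5):
            local = np.random.default_rng(seed)
            tree, aln = self._setup(local)
            ov_rank = srf.rank_fastest_first(srf.ov_scores(aln), True)
            rand_rank = local.permutation(aln.n_sites)
            s_ov = srf.removal_series(aln, ov_rank, tree, step=100)
            s_rand = srf.removal_series(aln, rand_rank, tree, step=100)
            wins.append(persistence(s_ov) - persistence(s_rand))
        assert np.median(wins) > 0

    def test_phylip_export(self, rng, tmp_path):
        tree, aln = self._setup(rng)
        ranking = srf.rank_fastest_first(srf.ov_scores(aln), True)
        series = srf.removal_series(aln, ranking, tree, step=300)
        paths = srf.export_series_phylip(series, aln, ranking, tmp_path)
        assert len(paths) == len(series.steps)
        back = pc.read_alignment(paths[0], format="phylip")
        assert back.n_sites == series.steps[0].n_sites
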