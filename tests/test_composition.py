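"""Composition-bias and lineage-rate diagnostic tests."""

import numpy as np
import pytest
from scipy import stats as sstats

from radsignal import composition as comp
from radsignal import phylo_core as pc
from radsignal import synthetic_data as sd


class TestProfiles:
    def test_examples(self):
        prof = comp.composition_profile(
            pc.Alignment.from_dict({"w": "AATT", "x": "AAAA",
                                    "y": "AACG", "z": "NN--"}))
        assert prof.gc_content["w"] == 0.0
        assert prof.at_skew["w"] == 0.0
        assert prof.at_skew["x"] == 1.0
        assert prof.gc_content["y"] == 50.0
        assert prof.at_skew["y"] == 1.0
        assert prof.gc_skew["y"] == 0.0
        assert prof.flagged_empty() == ["z"]

    def test_per_gene_counts(self):
        aln = pc.Alignment.from_dict(
            {"a": "AAGG", "b": "ATCG"},
            partition_map=pc.contiguous_partition({"g1": 2, "g2": 2}))
        prof = comp.composition_profile(aln, per_gene=True)
        assert prof.counts.loc[("a", "g1")].tolist() == [2, 0, 0, 0]
        assert prof.counts.loc[("b", "g2")].tolist() == [0, 1, 1, 0]

    def test_site_and_taxon_order_invariance(self, rng):
        aln = pc.Alignment.from_dict({"a": "ACGTTA", "b": "AGGCTA",
                                      "c": "TTGCAA"})
        perm = rng.permutation(6)
        shuffled = aln.subset_sites(perm).subset_taxa(["c", "a", "b"])
        p1 = comp.composition_profile(aln).counts.sort_index()
        p2 = comp.composition_profile(shuffled).counts.sort_index()
        assert (p1 == p2).all().all()

    def test_skew_sign_flip_and_gc_strand_invariance(self):
        aln = pc.Alignment.from_dict({"a": "AAAT", "b": "GGCA"})
        swapped = pc.Alignment(
            aln.taxa,
            np.vectorize({"A": "T", "T": "A", "C": "G", "G": "C"}.get)(
                aln.matrix))
        p1 = comp.composition_profile(aln)
        p2 = comp.composition_profile(swapped)
        assert np.allclose(p2.at_skew, -p1.at_skew)
        assert np.allclose(p2.gc_content, p1.gc_content)


class TestChiSquare:
    def test_identical_frequencies_stat_zero(self):
        prof = comp.composition_profile(
            pc.Alignment.from_dict({"a": "ACGT", "b": "ACGT", "c": "GTCA"}))
        stat, df, p = comp.chi_square_homogeneity(prof)
        assert stat == pytest.approx(0.0)
        assert p == 1.0

    def test_against_scipy_oracle(self):
        aln = pc.Alignment.from_dict({"a": "A" * 90 + "C" * 10,
                                      "b": "A" * 10 + "C" * 90})
        prof = comp.composition_profile(aln)
        stat, df, p = comp.chi_square_homogeneity(prof)
        table = prof.counts.to_numpy()[:, :2]
        ref = sstats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue)

    def test_calibration_on_stationary_data(self, rng):
        """Multinomial sampling from one frequency vector rejects at about
        the nominal 5% level."""
        freqs = np.array([0.3, 0.2, 0.2, 0.3])
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = rng.multinomial(500, freqs, size=8)
            prof = comp.CompositionProfile(
                comp.pd.DataFrame(counts, columns=list("ACGT")))
            _, _, p = comp.chi_square_homogeneity(prof)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.035)


class TestSkewClustering:
    def _profile(self, vectors):
        rows = []
        for taxon, v in vectors.items():
            for gi, skew in enumerate(v):
                a = 500 * (1 + skew) / 2
                t = 500 * (1 - skew) / 2
                rows.append((taxon, f"g{gi}", a, 0.0, 0.0, t))
        df = comp.pd.DataFrame(
            rows, columns=["taxon", "gene", "A", "C", "G", "T"]
        ).set_index(["taxon", "gene"])
        return comp.CompositionProfile(df)

    def test_identical_vectors_merge_at_zero(self):
        prof = self._profile({"a": [0.1, 0.2], "b": [0.1, 0.2],
                              "c": [0.5, 0.6]})
        cl = comp.skew_clustering(prof)
        assert cl.linkage[0, 2] == pytest.approx(0.0)

    def test_merge_heights_nondecreasing(self, rng):
        prof = self._profile({f"t{i}": rng.random(5).tolist()
                              for i in range(8)})
        cl = comp.skew_clustering(prof)
        assert (np.diff(cl.merge_heights()) >= -1e-12).all()

    def test_biased_clades_cluster_in_synthetic_data(self):
        hits = 0
        for seed in range(5):
            cfg = sd.RadiationConfig(seed=seed, n_genes=12)
            ds = sd.simulate_alignment(cfg)
            prof = comp.composition_profile(ds.alignment, per_gene=True)
            cl = comp.skew_clustering(prof)
            biased = [t for t, c in ds.clade_map.clade_of.items()
                      if c in cfg.biased_clades]
            hits += comp.clusters_unite(cl, biased)
        assert hits >= 4

    def test_too_few_taxa(self):
        prof = self._profile({"a": [0.1], "b": [0.2]})
        with pytest.raises(ValueError):
            comp.skew_clustering(prof)


class TestPhyloAnova:
    def test_f_matches_scipy_oracle(self):
        tree = pc.parse_tree("(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);")
        trait = {"a": 1.0, "b": 1.4, "c": 3.0, "d": 2.7, "e": 1.1, "f": 0.9}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2",
                  "e": "g1", "f": "g1"}
        f_obs, _ = comp.phylo_anova(trait, groups, tree, n_sim=10, seed=0)
        y1 = [trait[t] for t in "abef"]
        y2 = [trait[t] for t in "cd"]
        ref = sstats.f_oneway(y1, y2)
        assert f_obs == pytest.approx(ref.statistic)

    def test_nsim_zero_errors(self):
        tree = pc.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError):
            comp.phylo_anova({"a": 1, "b": 2, "c": 3, "d": 4},
                             {"a": "x", "b": "x", "c": "y", "d": "y"},
                             tree, n_sim=0)

    def test_zero_variance(self):
        tree = pc.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        f, p = comp.phylo_anova({"a": 1, "b": 1, "c": 1, "d": 1},
                                {"a": "x", "b": "x", "c": "y", "d": "y"},
                                tree, n_sim=10)
        assert p == 1.0

    def test_star_tree_calibration(self, rng):
        """On a star tree with homogeneous groups, the phylogenetic null
        matches the ordinary one: rejections near the nominal level."""
        n = 16
        star = pc.parse_tree(
            "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");")
        groups = {f"t{i}": ("g1" if i < n // 2 else "g2") for i in range(n)}
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            trait = {f"t{i}": rng.normal() for i in range(n)}
            _, p = comp.phylo_anova(trait, groups, star, n_sim=199,
                                    seed=int(rng.integers(2 ** 31)))
            rejections += p < 0.05
        assert rejections / n_rep < 0.12


class TestCladeRates:
    def _clade_map(self):
        return pc.CladeMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                            "o": "OUT"}, ["A", "B"], "OUT")

    def test_single_ultrametric_tree_equal_means(self):
        t = pc.parse_tree("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,o:3);")
        summary = comp.clade_rate_comparison([t] * 10, self._clade_map(),
                                             subsample_fraction=1.0)
        assert summary.table.loc["A", "mean"] == \
            pytest.approx(summary.table.loc["B", "mean"])
        assert summary.overlap_matrix().all().all()

    def test_full_subsample_is_identity(self, rng):
        from conftest import random_binary_tree
        trees = [random_binary_tree(["a1", "a2", "b1", "b2", "o"], rng)
                 for _ in range(10)]
        s1 = comp.clade_rate_comparison(trees, self._clade_map(),
                                        subsample_fraction=1.0, seed=1)
        s2 = comp.clade_rate_comparison(trees, self._clade_map(),
                                        subsample_fraction=1.0, seed=99)
        assert (s1.table == s2.table).all().all()

    def test_subsampling_uses_fraction(self, rng):
        from conftest import random_binary_tree
        trees = [random_binary_tree(["a1", "a2", "b1", "b2", "o"], rng)
                 for _ in range(20)]
        s = comp.clade_rate_comparison(trees, self._clade_map(),
                                       subsample_fraction=0.1, seed=3)
        assert s.table.loc["A", "n"] == 2 * 2  # 2 trees x 2 terminals

    def test_multiplier_visible_in_rate_trees(self):
        """Synthetic rate trees put the biased clades' root-to-tip means
        above the background clades'."""
        cfg = sd.RadiationConfig(seed=9, n_genes=1)
        _, rate_tree, _ = sd.generate_radiation_tree(cfg)
        ingroup = pc.prune_to_taxa(
            rate_tree, cfg.clade_map().ingroup_terminals)
        summary = comp.clade_rate_comparison([ingroup], cfg.clade_map(),
                                             subsample_fraction=1.0)
        ratio = summary.ratio(list(cfg.biased_clades),
                              [c for c in cfg.clade_labels
                               if c not in cfg.biased_clades])
        assert 1.4 <= ratio <= 1.8
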