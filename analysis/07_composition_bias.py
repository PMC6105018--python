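#!/usr/bin/env python
"""Systematic-bias diagnostics on the synthetic dataset.

Tests base-frequency homogeneity (chi-square), summarizes GC/AT
composition per clade group, clusters taxa by per-gene AT skew, runs a
simulation-based phylogenetic ANOVA on AT content (1,000 Brownian
simulations on the true chronogram), and compares clade-level molecular
rates from per-gene branch-length re-estimates.
"""

import os
import warnings

import numpy as np
import pandas as pd

from radsignal import composition as comp
from radsignal import likelihood as lk
from radsignal import phylo_core as pc

DATA = os.path.join("results", "synthetic")
OUT = "results"
BIASED = ("Iguania", "Serpentes")
N_GENES_RATE = 8
SEED = 4


def main() -> None:
    warnings.filterwarnings("ignore", message=".*no convergence.*")
    aln = pc.read_alignment(os.path.join(DATA, "alignment.nex"),
                            format="nexus")
    chrono = pc.read_tree(os.path.join(DATA, "chronogram.nwk"))
    chrono.is_rooted = True
    cm = pc.CladeMap.from_tsv(os.path.join(DATA, "clade_map.tsv"),
                              "Sphenodon")
    biased_taxa = {t for t, c in cm.clade_of.items() if c in BIASED}
    ingroup = cm.ingroup_terminals

    prof = comp.composition_profile(aln)
    prof.counts.assign(gc=prof.gc_content, at_skew=prof.at_skew).to_csv(
        os.path.join(OUT, "composition_profile.tsv"), sep="\t")
    stat, df, p = comp.chi_square_homogeneity(prof)
    print(f"chi-square homogeneity: X2 = {stat:.0f}, df = {df}, p = {p:.2e}")

    at = prof.at_content
    d_at = at[list(biased_taxa)].mean() - \
        at[[t for t in ingroup if t not in biased_taxa]].mean()
    print(f"biased clades are {d_at:.2f} percentage points AT-richer")

    gene_prof = comp.composition_profile(aln, per_gene=True)
    clustering = comp.skew_clustering(gene_prof)
    with open(os.path.join(OUT, "skew_dendrogram.nwk"), "w") as fh:
        fh.write(clustering.newick() + "\n")
    unite = comp.clusters_unite(clustering, sorted(biased_taxa))
    print(f"AT-skew clustering unites the biased clades: {unite}")

    ing_tree = pc.prune_to_taxa(chrono, ingroup)
    groups = {t: ("biased" if t in biased_taxa else "background")
              for t in ingroup}
    f_stat, p_phy = comp.phylo_anova(
        {t: float(at[t]) for t in ingroup}, groups, ing_tree,
        n_sim=1000, seed=SEED)
    print(f"phylogenetic ANOVA on AT content: F = {f_stat:.2f}, "
          f"p = {p_phy:.3f} (1,000 Brownian simulations)")

    # clade rates from per-gene branch-length re-estimation on the true
    # topology (one representative per clade + outgroup)
    reps = [sorted(cm.members(c))[0] for c in cm.clade_labels] + ["Sphenodon"]
    chrono_sub = pc.prune_to_taxa(chrono, reps)
    model = lk.SubstitutionModel.hky(3.0, np.array([0.28, 0.22, 0.22, 0.28]),
                                     gamma_shape=0.8, prop_invariant=0.2)
    trees = []
    for g in aln.genes[:N_GENES_RATE]:
        sub = aln.gene(g).subset_taxa(reps)
        if any((sub.row(t) == "?").all() for t in reps):
            continue
        topo = chrono_sub.clone(depth=1)
        for nd in topo.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = max(nd.edge.length * 0.002, 1e-4)
        opt, _ = lk.optimize_branch_lengths(sub, topo, model, max_rounds=2,
                                            brent_xatol=1e-4)
        og = next(lf for lf in opt.leaf_node_iter()
                  if lf.taxon.label == "Sphenodon")
        opt.to_outgroup_position(og, update_bipartitions=False,
                                 suppress_unifurcations=True)
        trees.append(pc.prune_to_taxa(opt, set(reps) - {"Sphenodon"}))
    summary = comp.clade_rate_comparison(trees, cm, subsample_fraction=1.0,
                                         seed=SEED)
    summary.table.to_csv(os.path.join(OUT, "clade_rates.tsv"), sep="\t")
    background = [c for c in cm.clade_labels if c not in BIASED]
    ratio = summary.ratio(list(BIASED), background)
    print(f"clade-rate comparison over {len(trees)} per-gene trees: "
          f"biased/background root-to-tip ratio = {ratio:.2f} "
          f"(planted multiplier 1.6 from the clade stems)")


if __name__ == "__main__":
    main()
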