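"""Compositional-bias and lineage-rate diagnostics.

Nonstationary base composition and unequal rates of molecular evolution
are classic sources of systematic error: lineages that independently
drift toward similar nucleotide usage, or that evolve much faster than
the rest, can be drawn together regardless of history (long-branch
attraction).  This module quantifies both: per-taxon composition (GC%,
AT/GC skew), a chi-square test of base-frequency homogeneity, hierarchical
clustering of per-gene AT-skew vectors, a simulation-based phylogenetic
ANOVA whose null F distribution comes from Brownian motion on the tree,
and clade-level root-to-tip rate comparison over a sample of trees.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy

from . import phylo_core
from .phylo_core import Alignment, CladeMap, DNA_ALPHABET


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompositionProfile:
    """Per-taxon (optionally per-gene) A/C/G/T counts with derived stats."""

    counts: pd.DataFrame  # index: taxon (or taxon, gene); columns A C G T

    @property
    def gc_content(self) -> pd.Series:
        c = self.counts
        tot = c.sum(axis=1)
        return 100.0 * (c["G"] + c["C"]) / tot.where(tot > 0)

    @property
    def at_skew(self) -> pd.Series:
        c = self.counts
        denom = (c["A"] + c["T"]).astype(float)
        return (c["A"] - c["T"]) / denom.where(denom > 0)

    @property
    def gc_skew(self) -> pd.Series:
        c = self.counts
        denom = (c["G"] + c["C"]).astype(float)
        return (c["G"] - c["C"]) / denom.where(denom > 0)

    @property
    def at_content(self) -> pd.Series:
        c = self.counts
        tot = c.sum(axis=1)
        return 100.0 * (c["A"] + c["T"]) / tot.where(tot > 0)

    def flagged_empty(self) -> list:
        return list(self.counts.index[self.counts.sum(axis=1) == 0])


def composition_profile(alignment: Alignment, per_gene: bool = False
                        ) -> CompositionProfile:
    """Unambiguous A/C/G/T counts per taxon (x gene when requested)."""
    if alignment.alphabet != DNA_ALPHABET:
        raise ValueError("composition profiles require DNA alignments")
    rows = []
    if per_gene:
        if not alignment.partition_map:
            raise ValueError("per-gene mode requires a partition map")
        for gene in alignment.genes:
            sub = alignment.gene(gene)
            for t in sub.taxa:
                seq = sub.row(t)
                rows.append((t, gene, *[int((seq == s).sum()) for s in "ACGT"]))
        df = pd.DataFrame(rows, columns=["taxon", "gene", "A", "C", "G", "T"]
                          ).set_index(["taxon", "gene"])
    else:
        for t in alignment.taxa:
            seq = alignment.row(t)
            rows.append((t, *[int((seq == s).sum()) for s in "ACGT"]))
        df = pd.DataFrame(rows, columns=["taxon", "A", "C", "G", "T"]
                          ).set_index("taxon")
    return CompositionProfile(df)


# ---------------------------------------------------------------------------
# chi-square homogeneity
# ---------------------------------------------------------------------------

def chi_square_homogeneity(profile: CompositionProfile
                           ) -> tuple[float, int, float]:
    """Chi-square test of base-frequency homogeneity across taxa.

    Builds the taxa x 4 contingency table of observed counts; expected
    cells come from the row/column margins.  Taxa with zero observed bases
    are excluded; an expected cell below one triggers a warning only.
    Returns (statistic, degrees of freedom, p-value).
    """
    table = profile.counts.to_numpy(dtype=float)
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("need counts for at least two taxa")
    colkeep = table.sum(axis=0) > 0
    table = table[:, colkeep]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected < 1).any():
        warnings.warn("expected cell count < 1; chi-square approximation "
                      "may be poor")
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sstats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# AT-skew clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SkewClustering:
    taxa: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    imputed: list[tuple[str, str]]  # (taxon, gene) entries filled in

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def flat_clusters(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.taxa, labels.tolist()))

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.taxa[node.id]
            return f"({walk(node.left)},{walk(node.right)})"

        return walk(tree) + ";"


def skew_clustering(profile_per_gene: CompositionProfile,
                    linkage_method: str = "average") -> SkewClustering:
    """Hierarchical clustering of per-gene AT-skew vectors.

    Taxa are points in gene-space (Euclidean metric); genes missing for a
    taxon are imputed with that taxon's across-gene mean skew and flagged.
    """
    skew = profile_per_gene.at_skew.unstack("gene")
    if skew.shape[0] < 3:
        raise ValueError("need at least three taxa to cluster")
    imputed = [(t, g) for t, g in zip(*np.where(skew.isna()))]
    imputed = [(skew.index[i], skew.columns[j]) for i, j in imputed]
    filled = skew.apply(lambda row: row.fillna(row.mean()), axis=1)
    if filled.isna().any().any():
        raise ValueError("taxon with no usable skew values")
    Z = hierarchy.linkage(filled.to_numpy(), method=linkage_method,
                          metric="euclidean")
    return SkewClustering(list(skew.index), Z, imputed)


def clusters_unite(clustering: SkewClustering, taxa: Sequence[str],
                   k: int = 2) -> bool:
    """True if ``taxa`` fall into one flat cluster that contains no other
    taxon, when the dendrogram is cut into ``k`` clusters."""
    flat = clustering.flat_clusters(k)
    ids = {flat[t] for t in taxa}
    if len(ids) != 1:
        return False
    cid = ids.pop()
    return all(flat[t] == cid for t in clustering.taxa if t in taxa) and \
        all(flat[t] != cid for t in clustering.taxa if t not in set(taxa))


# ---------------------------------------------------------------------------
# phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F statistic (between/within mean-square ratio)."""
    grand = values.mean()
    ssb = ssw = 0.0
    labels = np.unique(groups)
    for g in labels:
        sel = values[groups == g]
        ssb += len(sel) * (sel.mean() - grand) ** 2
        ssw += ((sel - sel.mean()) ** 2).sum()
    df_b = len(labels) - 1
    df_w = len(values) - len(labels)
    if df_w <= 0 or ssw == 0:
        return float("inf") if ssb > 0 else 0.0
    return float((ssb / df_b) / (ssw / df_w))


def _pic_sigma2(tree: dendropy.Tree, trait: Mapping[str, float]) -> float:
    """Brownian rate from phylogenetically independent contrasts."""
    contrasts = []

    def prune(node) -> tuple[float, float]:  # (value, extra branch length)
        if node.is_leaf():
            return float(trait[node.taxon.label]), node.edge.length or 0.0
        vals, lens = [], []
        for ch in node.child_nodes():
            v, ln = prune(ch)
            vals.append(v)
            lens.append(max(ln, 1e-12))
        # reduce multifurcations pairwise in order
        v0, l0 = vals[0], lens[0]
        for v1, l1 in zip(vals[1:], lens[1:]):
            contrasts.append((v0 - v1) / np.sqrt(l0 + l1))
            v0 = (v0 / l0 + v1 / l1) / (1.0 / l0 + 1.0 / l1)
            l0 = l0 * l1 / (l0 + l1)
        return v0, l0 + (node.edge.length or 0.0)

    prune(tree.seed_node)
    if not contrasts:
        raise ValueError("tree too small for contrasts")
    return float(np.mean(np.square(contrasts)))


def simulate_brownian(tree: dendropy.Tree, sigma2: float, n_sim: int,
                      rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip values on ``tree``: (taxa, n_sim x n_taxa)."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    values = np.zeros((n_sim, len(nodes)))
    taxa, cols = [], []
    for nd in nodes:
        if nd is tree.seed_node:
            continue
        i = index[id(nd)]
        p = index[id(nd.parent_node)]
        bl = max(nd.edge.length or 0.0, 0.0)
        values[:, i] = values[:, p] + rng.normal(
            0.0, np.sqrt(sigma2 * bl), size=n_sim)
        if nd.is_leaf():
            taxa.append(nd.taxon.label)
            cols.append(i)
    return taxa, values[:, cols]


def phylo_anova(trait_per_taxon: Mapping[str, float],
                groups: Mapping[str, str], tree: dendropy.Tree,
                n_sim: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Simulation-based phylogenetic ANOVA.

    F is the ordinary one-way statistic on the observed trait; the null
    distribution comes from Brownian-motion simulation on the tree with
    the contrasts-estimated rate.  Returns (F, p) with p the fraction of
    simulated F values at least as large as the observed one.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(taxa) - set(trait_per_taxon)
    if missing:
        raise ValueError(f"trait missing for taxa: {sorted(missing)}")
    y = np.array([trait_per_taxon[t] for t in taxa], dtype=float)
    g = np.array([groups[t] for t in taxa])
    if len(np.unique(g)) < 2:
        raise ValueError("need at least two groups")
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    f_obs = _anova_f(y, g)
    sigma2 = _pic_sigma2(tree, trait_per_taxon)
    rng = np.random.default_rng(seed)
    sim_taxa, sims = simulate_brownian(tree, sigma2, n_sim, rng)
    g_sim = np.array([groups[t] for t in sim_taxa])
    f_sim = np.array([_anova_f(sims[s], g_sim) for s in range(n_sim)])
    p = float(np.mean(f_sim >= f_obs))
    return f_obs, p


# ---------------------------------------------------------------------------
# clade rates from root-to-tip distances
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CladeRateSummary:
    """Pooled root-to-tip distance summaries per clade."""

    table: pd.DataFrame  # index clade; columns mean, median, lo95, hi95, n

    def interval(self, clade: str) -> tuple[float, float]:
        row = self.table.loc[clade]
        return float(row.lo95), float(row.hi95)

    def overlap_matrix(self) -> pd.DataFrame:
        clades = list(self.table.index)
        out = pd.DataFrame(True, index=clades, columns=clades)
        for a in clades:
            lo_a, hi_a = self.interval(a)
            for b in clades:
                lo_b, hi_b = self.interval(b)
                out.loc[a, b] = not (hi_a < lo_b or hi_b < lo_a)
        return out

    def ratio(self, clades_a: Sequence[str], clades_b: Sequence[str]) -> float:
        """Mean rate of group a over group b."""
        ma = self.table.loc[list(clades_a), "mean"].mean()
        mb = self.table.loc[list(clades_b), "mean"].mean()
        return float(ma / mb)


def clade_rate_comparison(tree_sample: Sequence[dendropy.Tree],
                          clade_map: CladeMap,
                          subsample_fraction: float = 0.10,
                          seed: int = 0) -> CladeRateSummary:
    """Clade-level molecular rate comparison over a sample of trees.

    A fraction of the trees is subsampled at random; root-to-tip distances
    of every member terminal in every sampled tree are pooled per clade,
    and the mean, median and central 95% interval reported.  Trees missing
    a clade entirely are skipped for that clade.
    """
    trees = list(tree_sample)
    if len(trees) < 1:
        raise ValueError("empty tree sample")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(subsample_fraction * len(trees))))
    chosen = rng.choice(len(trees), size=k, replace=False) \
        if k < len(trees) else np.arange(len(trees))
    pooled: dict[str, list[float]] = {c: [] for c in clade_map.clade_labels}
    for ti in chosen:
        r2t = phylo_core.root_to_tip_distances(trees[ti])
        for clade in clade_map.clade_labels:
            members = [t for t in clade_map.members(clade) if t in r2t]
            if not members:
                continue
            pooled[clade].extend(r2t[t] for t in members)
    rows = []
    for clade, vals in pooled.items():
        if not vals:
            rows.append((clade, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        v = np.asarray(vals)
        rows.append((clade, v.mean(), np.median(v),
                     np.percentile(v, 2.5), np.percentile(v, 97.5), len(v)))
    table = pd.DataFrame(rows, columns=["clade", "mean", "median",
                                        "lo95", "hi95", "n"]).set_index("clade")
    return CladeRateSummary(table)
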