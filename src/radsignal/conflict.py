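"""Gene-tree conflict quantification.

How much do individual gene trees disagree, and where?  This module
computes the pairwise Robinson-Foulds distance matrix over a set of gene
trees (optionally with flagged reference topologies appended), condenses
it into a two-dimensional treespace by classical multidimensional scaling,
tabulates bipartition frequencies for supernetwork construction, and
scores every node of a reference tree by its gene support frequency (GSF):
the fraction of eligible gene trees that display it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phylo_core


# ---------------------------------------------------------------------------
# RF matrix
# ---------------------------------------------------------------------------

def rf_matrix(trees: Sequence[dendropy.Tree],
              reference_trees: Sequence[dendropy.Tree] = (),
              labels: Sequence[str] | None = None,
              normalized: bool = True,
              ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Symmetric pairwise RF matrix with shared-leaf pruning.

    Reference trees (concatenated, morphological...) are appended after
    the gene trees and flagged in the returned boolean mask.  Pairs with
    fewer than four shared leaves get NaN.
    """
    all_trees = list(trees) + list(reference_trees)
    n = len(all_trees)
    if n < 2:
        raise ValueError("need at least two trees")
    if labels is None:
        labels = [f"gene_{i + 1}" for i in range(len(trees))] + \
            [f"ref_{i + 1}" for i in range(len(reference_trees))]
    labels = list(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = phylo_core.rf_distance(all_trees[i], all_trees[j],
                                           normalized=normalized)
            except phylo_core.UndefinedDistanceError:
                d = np.nan
            D[i, j] = D[j, i] = d
    is_ref = np.array([False] * len(trees) + [True] * len(reference_trees))
    return D, labels, is_ref


def mean_offdiagonal(D: np.ndarray) -> float:
    iu = np.triu_indices_from(D, k=1)
    vals = D[iu]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# treespace embedding
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TreespaceEmbedding:
    coordinates: np.ndarray  # (n_trees, dims)
    stress: float            # Kruskal stress-1
    eigenvalues: np.ndarray
    imputed: bool = False


def embed_treespace(D: np.ndarray, dims: int = 2) -> TreespaceEmbedding:
    """Classical MDS (double centering + top eigenvectors) of a distance
    matrix; missing entries are imputed with the matrix mean and flagged.
    Rank-deficient inputs yield fewer axes with a warning via stress=0
    handling upstream."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    imputed = False
    if np.isnan(D).any():
        fill = np.nanmean(D[np.triu_indices(n, k=1)])
        D = np.where(np.isnan(D), fill, D)
        np.fill_diagonal(D, 0.0)
        imputed = True
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    lam, V = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    pos = lam > max(lam.max(), 0) * 1e-12
    use = min(dims, int(pos.sum())) or 1
    coords = V[:, :use] * np.sqrt(np.maximum(lam[:use], 0.0))
    # Kruskal stress-1 between embedded and input distances
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    denom = (D[iu] ** 2).sum()
    stress = float(np.sqrt(((D[iu] - emb[iu]) ** 2).sum() / denom)) \
        if denom > 0 else 0.0
    return TreespaceEmbedding(coords, stress, lam, imputed)


# ---------------------------------------------------------------------------
# split frequencies
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TaggedSplit:
    """A bipartition with both sides stated explicitly (trees in the set
    may sample different taxa, so the universe is per-split)."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise ValueError("split sides overlap")
        # canonical order of sides for hashing/equality
        if min(self.side_a) > min(self.side_b):
            a, b = self.side_a, self.side_b
            object.__setattr__(self, "side_a", b)
            object.__setattr__(self, "side_b", a)

    @property
    def taxa(self) -> frozenset[str]:
        return self.side_a | self.side_b


@dataclasses.dataclass
class SplitFrequencyTable:
    frequencies: dict[TaggedSplit, float]
    n_applicable: dict[TaggedSplit, int]
    universe: frozenset[str]

    def frame(self) -> pd.DataFrame:
        rows = [("|".join(sorted(s.side_a)), "|".join(sorted(s.side_b)),
                 self.n_applicable[s], f)
                for s, f in self.frequencies.items()]
        return pd.DataFrame(rows, columns=["side_a", "side_b",
                                           "n_applicable", "frequency"])


def _displays(tree: dendropy.Tree, split: TaggedSplit,
              tree_splits_cache: dict | None = None) -> bool:
    """Does the tree, restricted to the split's taxa, show the split?"""
    leaves = phylo_core.leaf_labels(tree)
    if not split.taxa <= leaves:
        return False
    if leaves == split.taxa:
        restricted = tree
    else:
        restricted = phylo_core.prune_to_taxa(tree, split.taxa)
    if len(split.side_a) < 2 or len(split.side_b) < 2:
        return True  # trivial on the restricted view
    return phylo_core.canonical_split(split.side_a, split.taxa) in \
        phylo_core.nontrivial_splits(restricted)


def split_frequencies(gene_trees: Sequence[dendropy.Tree]
                      ) -> SplitFrequencyTable:
    """Bipartition frequencies across a gene-tree set.

    Candidate splits are the nontrivial splits of each tree (stated on
    that tree's own taxa).  The frequency of a split is the number of
    trees displaying it over the number of trees sampling all its taxa.
    """
    trees = list(gene_trees)
    if len(trees) < 2:
        raise ValueError("need at least two gene trees")
    candidates: set[TaggedSplit] = set()
    for t in trees:
        universe = phylo_core.leaf_labels(t)
        for side in phylo_core.nontrivial_splits(t):
            candidates.add(TaggedSplit(side, universe - side))
    freqs: dict[TaggedSplit, float] = {}
    napp: dict[TaggedSplit, int] = {}
    for s in candidates:
        applicable = [t for t in trees if s.taxa <= phylo_core.leaf_labels(t)]
        shown = sum(_displays(t, s) for t in applicable)
        napp[s] = len(applicable)
        freqs[s] = shown / len(applicable) if applicable else 0.0
    universe = frozenset().union(*[phylo_core.leaf_labels(t) for t in trees])
    return SplitFrequencyTable(freqs, napp, universe)


def export_splits_nexus(table: SplitFrequencyTable, path) -> int:
    """NEXUS splits block (SplitsTree st_splits dialect) for network layout.

    Only splits spanning the full taxon universe can be written; returns
    the number written.
    """
    taxa = sorted(table.universe)
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    full = [(s, f) for s, f in table.frequencies.items()
            if s.taxa == table.universe]
    with open(path, "w") as fh:
        fh.write("#nexus\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\nTAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND; [Taxa]\n\nBEGIN st_splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(full)};\n")
        fh.write("FORMAT labels=no weights=yes;\nMATRIX\n")
        for k, (s, f) in enumerate(full, 1):
            side = sorted(idx[t] for t in s.side_a)
            fh.write(f"[{k}, size={len(side)}]\t{f:.6f}\t"
                     + " ".join(map(str, side)) + ",\n")
        fh.write(";\nEND; [st_splits]\n")
    return len(full)


# ---------------------------------------------------------------------------
# gene support frequency
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NodeSupport:
    clade: frozenset[str]
    eligible: int
    supporting: int

    @property
    def gsf(self) -> float | None:
        return self.supporting / self.eligible if self.eligible else None


def gene_support_frequency(gene_trees: Sequence[dendropy.Tree],
                           reference_tree: dendropy.Tree
                           ) -> dict[frozenset[str], NodeSupport]:
    """Gene support frequency for every internal node of a rooted reference.

    A gene is eligible for a node when it samples all the node's terminals
    plus at least one outside terminal; it supports the node when its tree,
    restricted to the gene's taxa, shows the clade as monophyletic.  Nodes
    with no eligible gene report GSF None.
    """
    ref_leaves = phylo_core.leaf_labels(reference_tree)
    out: dict[frozenset[str], NodeSupport] = {}
    gene_leafsets = [phylo_core.leaf_labels(t) for t in gene_trees]
    for node in reference_tree.preorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(clade) < 2 or clade == ref_leaves:
            continue
        eligible = supporting = 0
        for t, leaves in zip(gene_trees, gene_leafsets):
            if not clade <= leaves or not (leaves - clade):
                continue
            eligible += 1
            if phylo_core.is_monophyletic(t, clade):
                supporting += 1
        out[clade] = NodeSupport(clade, eligible, supporting)
    return out


def gsf_frame(supports: dict[frozenset[str], NodeSupport]) -> pd.DataFrame:
    rows = [("|".join(sorted(c)), len(c), s.eligible, s.supporting,
             np.nan if s.gsf is None else s.gsf)
            for c, s in supports.items()]
    return pd.DataFrame(rows, columns=["clade", "size", "eligible_genes",
                                       "supporting_genes", "gsf"])
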