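"""Tree-independent site-rate proxies and ranked fast-site removal.

OV (observed variability) scores a site by its pairwise mismatch fraction
across terminals; TIGER scores it by how well the taxon partitions implied
by other sites agree with (nest inside) its own partition.  Fast sites are
then stripped in fixed-size steps, a tree is re-inferred at each step
(neighbor joining on ML distances by default), and the persistence of a
reference tree's backbone splits is recorded — the collapse point reveals
how much of the deep structure rests on the noisiest characters.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import dendropy
import numpy as np
from scipy import stats as sstats

from . import phylo_core
from .phylo_core import Alignment


# ---------------------------------------------------------------------------
# per-site scores
# ---------------------------------------------------------------------------

def ov_scores(alignment: Alignment) -> np.ndarray:
    """Observed variability: mismatching fraction of observed taxon pairs.

    Gaps/missing/ambiguous cells are excluded from pair counts.  Sites with
    fewer than two observed states return NaN.
    """
    obs = alignment.observed_mask()
    n_sites = alignment.n_sites
    out = np.full(n_sites, np.nan)
    for j in range(n_sites):
        col = alignment.matrix[obs[:, j], j]
        n = len(col)
        if n < 2:
            continue
        _, counts = np.unique(col, return_counts=True)
        total_pairs = n * (n - 1) // 2
        match_pairs = int((counts * (counts - 1) // 2).sum())
        out[j] = (total_pairs - match_pairs) / total_pairs
    return out


def _site_state_sets(alignment: Alignment) -> list[list[int]]:
    """Per site, the taxon bitmask of each observed state class."""
    obs = alignment.observed_mask()
    out: list[list[int]] = []
    for j in range(alignment.n_sites):
        masks: dict[str, int] = {}
        for i in np.where(obs[:, j])[0]:
            s = alignment.matrix[i, j]
            masks[s] = masks.get(s, 0) | (1 << int(i))
        out.append(list(masks.values()))
    return out


def tiger_scores(alignment: Alignment) -> np.ndarray:
    """TIGER agreement scores in [0, 1]; higher = slower.

    For sites i, j the partition agreement pa(j -> i) is the fraction of
    j's state sets that nest inside some state set of i; the score of i is
    the mean of pa(j -> i) over all other sites j.  Taxa unobserved at a
    site are excluded from that site's sets.
    """
    if alignment.n_sites < 2:
        raise ValueError("TIGER needs at least two sites")
    sets = _site_state_sets(alignment)
    n = alignment.n_sites
    scores = np.zeros(n)
    for i in range(n):
        Si = sets[i]
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            Sj = sets[j]
            if not Sj:
                continue
            hits = 0
            for s in Sj:
                for t in Si:
                    if s & t == s:
                        hits += 1
                        break
            acc += hits / len(Sj)
        scores[i] = acc / (n - 1)
    return scores


def rank_fastest_first(scores: np.ndarray, higher_is_faster: bool) -> np.ndarray:
    """Site order fastest -> slowest; ties broken by original site index."""
    scores = np.asarray(scores, dtype=float)
    key = np.where(np.isnan(scores),
                   -np.inf if higher_is_faster else np.inf, scores)
    order = np.argsort(-key if higher_is_faster else key, kind="stable")
    return order


# ---------------------------------------------------------------------------
# distances and NJ re-inference
# ---------------------------------------------------------------------------

_JC_CAP = 5.0


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise Jukes-Cantor ML distances over shared observed sites."""
    obs = alignment.observed_mask()
    n = alignment.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = _JC_CAP
                continue
            p = float((alignment.matrix[i, both] !=
                       alignment.matrix[j, both]).sum()) / m
            arg = 1.0 - 4.0 * p / 3.0
            d = -0.75 * np.log(arg) if arg > np.exp(-4 * _JC_CAP / 3) else _JC_CAP
            D[i, j] = D[j, i] = min(d, _JC_CAP)
    return D


def ml_distance_matrix(alignment: Alignment, model) -> np.ndarray:
    """Pairwise ML distances under an engine substitution model.

    For each taxon pair the 4x4 (or kxk) joint pattern counts over shared
    observed sites are collected and the branch length maximizing the
    two-taxon likelihood (rate-category mixture included) is found by
    bounded Brent search.  Unlike the closed-form JC distance this does
    not saturate under among-site rate variation.
    """
    from scipy import optimize

    states = list(model.states)
    k = len(states)
    code = np.full(256, -1, dtype=int)
    for i, s in enumerate(states):
        code[ord(s)] = i
        code[ord(s.lower())] = i
    enc = np.full(alignment.matrix.shape, -1, dtype=int)
    for ch in np.unique(alignment.matrix):
        if ch and ord(ch) < 256:
            enc[alignment.matrix == ch] = code[ord(ch)]
    rates, weights = model.rate_categories()
    pi = model.equilibrium_frequencies
    n = alignment.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                D[i, j] = D[j, i] = _JC_CAP
                continue
            N = np.zeros((k, k))
            np.add.at(N, (a[ok], b[ok]), 1.0)

            def negll(d: float) -> float:
                P = model.transition_matrices(d * rates)  # (ncat, k, k)
                mix = np.einsum("c,x,cxy->xy", weights, pi, P)
                return -float((N * np.log(np.maximum(mix, 1e-300))).sum())

            res = optimize.minimize_scalar(negll, bounds=(1e-8, _JC_CAP),
                                           method="bounded",
                                           options={"xatol": 1e-6})
            D[i, j] = D[j, i] = float(res.x)
    return D


def nj_from_distances(D: np.ndarray, ids: Sequence[str]) -> dendropy.Tree:
    """Neighbor joining (scikit-bio) on a distance matrix; tiny negative
    branch lengths are clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    dm = DistanceMatrix(np.asarray(D, dtype=float), ids=list(ids))
    newick = str(skbio_nj(dm)).strip()
    tree = phylo_core.parse_tree(newick)
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            node.edge.length = 0.0
    return tree


def nj_tree(alignment: Alignment, model=None) -> dendropy.Tree:
    """Neighbor-joining tree on ML distances (closed-form JC by default,
    or any engine model via :func:`ml_distance_matrix`)."""
    D = jc_distance_matrix(alignment) if model is None \
        else ml_distance_matrix(alignment, model)
    return nj_from_distances(D, alignment.taxa)


# ---------------------------------------------------------------------------
# removal series
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RemovalStep:
    n_removed: int
    n_sites: int
    tree: dendropy.Tree
    split_presence: dict[frozenset[str], bool]


@dataclasses.dataclass
class RemovalSeries:
    steps: list[RemovalStep]
    reference_splits: set[frozenset[str]]
    truncated: bool = False

    def presence_frame(self):
        import pandas as pd

        rows = []
        for st in self.steps:
            for split, present in st.split_presence.items():
                rows.append((st.n_removed, st.n_sites,
                             "|".join(sorted(split)), present))
        return pd.DataFrame(rows, columns=["n_removed", "sites_remaining",
                                           "split", "present"])


def removal_series(alignment: Alignment, ranking: np.ndarray,
                   reference_tree: dendropy.Tree, step: int = 500,
                   inference: Callable[[Alignment], dendropy.Tree] = nj_tree,
                   backbone_splits: set[frozenset[str]] | None = None,
                   ) -> RemovalSeries:
    """Progressive fastest-site removal with re-inference.

    ``ranking`` orders all sites fastest -> slowest.  Step 0 keeps the full
    alignment; each later step drops the next ``step`` fastest sites and
    records which reference backbone splits persist in the re-inferred
    tree.  The series stops (flagged truncated) once no variable site is
    left.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    ranking = np.asarray(ranking, dtype=int)
    if sorted(ranking.tolist()) != list(range(alignment.n_sites)):
        raise ValueError("ranking must be a permutation of all site indices")
    if step > alignment.n_sites:
        raise ValueError("step exceeds alignment length")
    if backbone_splits is None:
        backbone_splits = phylo_core.nontrivial_splits(reference_tree)
    ref_taxa = phylo_core.leaf_labels(reference_tree)

    steps: list[RemovalStep] = []
    truncated = False
    n_removed = 0
    while n_removed < alignment.n_sites:
        keep = np.sort(ranking[n_removed:])
        sub = alignment.subset_sites(keep)
        if len(sub.variable_sites()) == 0:
            truncated = True
            warnings.warn("removal series truncated: no variable sites left")
            break
        tree = inference(sub)
        tree_splits = phylo_core.nontrivial_splits(tree)
        presence = {}
        for split in backbone_splits:
            canon = phylo_core.canonical_split(split, ref_taxa)
            presence[canon] = canon in tree_splits
        steps.append(RemovalStep(n_removed, sub.n_sites, tree, presence))
        n_removed += step
    return RemovalSeries(steps, set(backbone_splits), truncated)


def export_series_phylip(series: RemovalSeries, alignment: Alignment,
                         ranking: np.ndarray, directory) -> list[str]:
    """Write each step's matrix as relaxed PHYLIP (hook for external ML)."""
    import os

    paths = []
    for st in series.steps:
        keep = np.sort(np.asarray(ranking[st.n_removed:], dtype=int))
        sub = alignment.subset_sites(keep)
        path = os.path.join(str(directory), f"removed_{st.n_removed}.phy")
        phylo_core.write_phylip(sub, path)
        paths.append(path)
    return paths


def rank_vs_truth(scores: np.ndarray, true_rates: np.ndarray,
                  higher_is_faster: bool = True) -> float:
    """Spearman correlation between a score and the true per-site rate,
    signed so that perfect fast-site identification gives +1."""
    scores = np.asarray(scores, dtype=float)
    true_rates = np.asarray(true_rates, dtype=float)
    ok = ~np.isnan(scores)
    if np.nanstd(scores[ok]) == 0:
        warnings.warn("constant scores: rank correlation undefined")
        return float("nan")
    rho, _ = sstats.spearmanr(scores[ok], true_rates[ok])
    return float(rho if higher_is_faster else -rho)
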