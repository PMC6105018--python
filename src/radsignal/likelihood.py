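"""Small phylogenetic likelihood engine.

Implements Felsenstein's pruning algorithm for time-reversible
substitution models (JC, HKY, GTR for nucleotides; symmetric Mk for
discrete characters) with discrete-gamma rate variation and an optional
invariant class, per-site log-likelihoods with numerical scaling,
coordinate-wise branch-length optimization on a fixed topology, per-site
ML rate estimation on a fixed chronogram, and exhaustive evaluation of a
constrained topology class.

The rate matrix is always normalized so the expected substitution rate at
equilibrium equals one; branch lengths are therefore expected numbers of
substitutions per site (or, on a chronogram, durations to be multiplied by
a rate).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammaincc, gammainc

from . import phylo_core
from .phylo_core import Alignment, DNA_ALPHABET, DNA_AMBIGUITY, DNA_MISSING

_MIN_BL = 1e-8
_MAX_BL = 20.0


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a mean-one
    gamma distribution (the standard discrete-gamma approximation)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    from scipy.stats import gamma as gamma_dist

    bounds = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha,
                            scale=1.0 / alpha)
    # E[X 1{X < b}] for X ~ Gamma(alpha, 1/alpha) equals gammainc(alpha+1, alpha*b)
    cum = gammainc(alpha + 1, alpha * bounds)
    cum[0], cum[-1] = 0.0, 1.0
    rates = ncat * np.diff(cum)
    return rates / rates.mean()


@dataclasses.dataclass
class SubstitutionModel:
    """Time-reversible k-state model with optional +Gamma and +I.

    ``exchangeabilities`` is the upper triangle of the symmetric
    exchangeability matrix in the order (AC, AG, AT, CG, CT, GT) for DNA,
    or a single shared value for JC/Mk.
    """

    exchangeabilities: np.ndarray
    equilibrium_frequencies: np.ndarray
    gamma_shape: float | None = None
    prop_invariant: float | None = None
    n_rate_categories: int = 4
    states: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        k = len(self.states)
        self.equilibrium_frequencies = np.asarray(
            self.equilibrium_frequencies, dtype=float)
        if self.equilibrium_frequencies.shape != (k,):
            raise ValueError("frequency vector length must match state count")
        if abs(self.equilibrium_frequencies.sum() - 1.0) > 1e-8 or \
                (self.equilibrium_frequencies <= 0).any():
            raise ValueError("frequencies must be positive and sum to 1")
        ex = np.asarray(self.exchangeabilities, dtype=float)
        npair = k * (k - 1) // 2
        if ex.size == 1:
            ex = np.full(npair, float(ex.reshape(())))
        if ex.shape != (npair,):
            raise ValueError(f"need {npair} exchangeabilities")
        self.exchangeabilities = ex
        if self.prop_invariant is not None and not 0 <= self.prop_invariant < 1:
            raise ValueError("prop_invariant must lie in [0, 1)")
        self._decompose()

    # -- constructors ------------------------------------------------------
    @classmethod
    def jc(cls, gamma_shape=None, prop_invariant=None, ncat=4) -> "SubstitutionModel":
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape, prop_invariant, ncat)

    @classmethod
    def hky(cls, kappa: float, freqs, gamma_shape=None, prop_invariant=None,
            ncat=4) -> "SubstitutionModel":
        # pair order AC, AG, AT, CG, CT, GT; transitions are AG and CT
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls(ex, freqs, gamma_shape, prop_invariant, ncat)

    @classmethod
    def gtr(cls, exchangeabilities, freqs, gamma_shape=None,
            prop_invariant=None, ncat=4) -> "SubstitutionModel":
        return cls(exchangeabilities, freqs, gamma_shape, prop_invariant, ncat)

    @classmethod
    def mk(cls, n_states: int, gamma_shape=None, ncat=4) -> "SubstitutionModel":
        if n_states < 2:
            raise ValueError("Mk needs >=2 states")
        states = "".join(str(i) for i in range(n_states)) if n_states <= 10 \
            else "".join(chr(ord("A") + i) for i in range(n_states))
        k = n_states
        return cls(np.ones(k * (k - 1) // 2), np.full(k, 1.0 / k),
                   gamma_shape, None, ncat, states=states)

    # -- rate matrix -------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to mean rate one at equilibrium."""
        k = self.n_states
        pi = self.equilibrium_frequencies
        Q = np.zeros((k, k))
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                s = self.exchangeabilities[idx]
                Q[i, j] = s * pi[j]
                Q[j, i] = s * pi[i]
                idx += 1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _decompose(self) -> None:
        # reversible Q diagonalized through the pi-symmetrized form
        Q = self.rate_matrix()
        pi = self.equilibrium_frequencies
        sq = np.sqrt(pi)
        # similarity transform diag(sqrt(pi)) Q diag(1/sqrt(pi)) is
        # symmetric for a reversible Q
        B = Q * (sq[:, None] / sq[None, :])
        B = (B + B.T) / 2.0
        lam, V = np.linalg.eigh(B)
        self._eigvals = lam
        self._U = V / sq[:, None]          # Q = U diag(lam) Uinv
        self._Uinv = V.T * sq[None, :]

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths -> shape (..., k, k)."""
        lengths = np.asarray(lengths, dtype=float)
        e = np.exp(lengths[..., None] * self._eigvals)  # (..., k)
        P = np.einsum("ik,...k,kj->...ij", self._U, e, self._Uinv)
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the site-rate mixture, overall mean one."""
        if self.gamma_shape is not None:
            rates = discrete_gamma_rates(self.gamma_shape,
                                         self.n_rate_categories)
            weights = np.full(self.n_rate_categories,
                              1.0 / self.n_rate_categories)
        else:
            rates = np.array([1.0])
            weights = np.array([1.0])
        p_inv = self.prop_invariant or 0.0
        if p_inv > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
            weights = np.concatenate([[p_inv], weights * (1.0 - p_inv)])
        return rates, weights

    @property
    def n_free_parameters(self) -> int:
        """Free model parameters (for BIC); branch lengths counted separately."""
        k = self.n_states
        ex = self.exchangeabilities
        n = 0
        if not np.allclose(ex, ex[0]):
            n += len(np.unique(np.round(ex, 12))) - 1
        if not np.allclose(self.equilibrium_frequencies, 1.0 / k):
            n += k - 1
        if self.gamma_shape is not None:
            n += 1
        if self.prop_invariant is not None:
            n += 1
        return n


# ---------------------------------------------------------------------------
# indexed trees and tip encodings
# ---------------------------------------------------------------------------

class IndexedTree:
    """Array-indexed view of a dendropy tree for fast pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        self.lengths = np.zeros(len(self.nodes))
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.leaf_ids: dict[str, int] = {}
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                self.parent[i] = self.index[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
                self.lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                self.leaf_ids[nd.taxon.label] = i
        self.root = len(self.nodes) - 1
        self.edge_ids = [i for i in range(len(self.nodes)) if i != self.root]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_tree(self) -> dendropy.Tree:
        """Rebuild a dendropy tree carrying the current branch lengths."""

        def nw(i: int) -> str:
            if not self.children[i]:
                name = self.nodes[i].taxon.label
                return f"{name}:{self.lengths[i]:.12g}"
            inner = ",".join(nw(c) for c in self.children[i])
            if i == self.root:
                return f"({inner})"
            return f"({inner}):{self.lengths[i]:.12g}"

        t = phylo_core.parse_tree(nw(self.root) + ";")
        t.is_rooted = True
        return t


def encode_tips(alignment: Alignment, states: str = DNA_ALPHABET) -> np.ndarray:
    """Partial-likelihood encodings of tip characters.

    Returns (n_taxa, n_sites, k) with ones over the states compatible with
    each observed character; gaps/missing/unknown become all-ones.
    """
    k = len(states)
    lookup: dict[str, np.ndarray] = {}
    for i, s in enumerate(states):
        v = np.zeros(k)
        v[i] = 1.0
        lookup[s] = v
        lookup[s.lower()] = v
    if states == DNA_ALPHABET:
        for code, compat in DNA_AMBIGUITY.items():
            v = np.zeros(k)
            for s in compat:
                v[states.index(s)] = 1.0
            lookup[code] = v
            lookup[code.lower()] = v
    allset = np.ones(k)
    out = np.ones((alignment.n_taxa, alignment.n_sites, k))
    for ch in np.unique(alignment.matrix):
        vec = lookup.get(str(ch), allset)
        out[alignment.matrix == ch] = vec
    return out


def compress_patterns(alignment: Alignment) -> tuple[Alignment, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and the site -> pattern map."""
    cols = ["".join(alignment.matrix[:, j]) for j in range(alignment.n_sites)]
    uniq, inverse, counts = np.unique(cols, return_inverse=True,
                                      return_counts=True)
    mat = np.array([list(c) for c in uniq], dtype="<U1").T
    patt = Alignment(list(alignment.taxa), mat, alignment.alphabet)
    return patt, counts.astype(float), inverse


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _site_logliks(itree: IndexedTree, tips: np.ndarray,
                  model: SubstitutionModel,
                  lengths: np.ndarray | None = None) -> np.ndarray:
    """Per-pattern log-likelihoods under the rate-category mixture."""
    if lengths is None:
        lengths = itree.lengths
    rates, weights = model.rate_categories()
    ncat = len(rates)
    n_sites, k = tips.shape[1], model.n_states
    pi = model.equilibrium_frequencies
    # transition matrices for every (node, category)
    P = model.transition_matrices(np.outer(lengths, rates))  # (nodes, ncat, k, k)
    partial = np.empty((itree.n_nodes, ncat, n_sites, k))
    logscale = np.zeros((ncat, n_sites))
    for i in range(itree.n_nodes):
        ch = itree.children[i]
        if not ch:
            partial[i] = np.broadcast_to(tips_for(itree, tips, i), (ncat, n_sites, k))
            continue
        acc = np.ones((ncat, n_sites, k))
        for c in ch:
            # message from child c through its branch
            acc = acc * np.einsum("rij,rsj->rsi", P[c], partial[c])
        # rescale to avoid underflow
        m = acc.max(axis=2)
        tiny = m <= 0
        if tiny.any():
            m = np.where(tiny, 1.0, m)
        acc = acc / m[:, :, None]
        logscale += np.log(m)
        partial[i] = acc
    root = partial[itree.root] @ pi  # (ncat, n_sites)
    site_l = (weights[:, None] * root * np.exp(logscale - logscale.max(axis=0))).sum(axis=0)
    return np.log(site_l) + logscale.max(axis=0)


def tips_for(itree: IndexedTree, tips: np.ndarray, node_id: int) -> np.ndarray:
    label = itree.nodes[node_id].taxon.label
    return tips[_taxon_row(itree, label)]


def _taxon_row(itree: IndexedTree, label: str) -> int:
    return itree._tip_rows[label]


def _prepare(alignment: Alignment, tree: dendropy.Tree) -> IndexedTree:
    leaves = phylo_core.leaf_labels(tree)
    missing = leaves - set(alignment.taxa)
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    return IndexedTree(tree)


@dataclasses.dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods for one (tree, model) pair."""

    log_likelihoods: np.ndarray
    tree_id: str = ""
    gene: str = ""

    @property
    def total(self) -> float:
        return float(self.log_likelihoods.sum())


def site_log_likelihoods(alignment: Alignment, tree: dendropy.Tree,
                         model: SubstitutionModel,
                         tree_id: str = "", gene: str = "") -> SiteLikelihoodTable:
    """Felsenstein pruning per-site log-likelihoods (gamma mixture, scaled)."""
    itree = _prepare(alignment, tree)
    patt, counts, inverse = compress_patterns(alignment)
    tips_p = encode_tips(patt, model.states)
    itree._tip_rows = {lab: patt.taxa.index(lab)
                       for lab in phylo_core.leaf_labels(tree)}
    per_pattern = _site_logliks(itree, tips_p, model)
    if not np.isfinite(per_pattern).all():
        raise FloatingPointError("non-finite site likelihood")
    return SiteLikelihoodTable(per_pattern[inverse], tree_id=tree_id, gene=gene)


def total_log_likelihood(alignment: Alignment, tree: dendropy.Tree,
                         model: SubstitutionModel) -> float:
    return site_log_likelihoods(alignment, tree, model).total


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------

def optimize_branch_lengths(alignment: Alignment, topology: dendropy.Tree,
                            model: SubstitutionModel, tol: float = 1e-6,
                            max_rounds: int = 20, brent_xatol: float = 1e-8,
                            ) -> tuple[dendropy.Tree, float]:
    """Coordinate-wise (Brent) branch-length optimization on a fixed topology.

    Returns a new tree and its log-likelihood; the result never falls below
    the starting log-likelihood.  Branches start from their current lengths
    (missing lengths from 0.05).
    """
    itree = _prepare(alignment, topology)
    patt, counts, _ = compress_patterns(alignment)
    tips = encode_tips(patt, model.states)
    itree._tip_rows = {lab: patt.taxa.index(lab)
                       for lab in phylo_core.leaf_labels(topology)}
    lengths = itree.lengths.copy()
    lengths[lengths <= 0] = 0.05
    lengths[itree.root] = 0.0

    def total(ls: np.ndarray) -> float:
        return float(_site_logliks(itree, tips, model, ls) @ counts)

    cur = total(lengths)
    for _ in range(max_rounds):
        prev = cur
        for e in itree.edge_ids:
            def f(x: float, _e=e) -> float:
                ls = lengths.copy()
                ls[_e] = x
                return -total(ls)

            res = optimize.minimize_scalar(
                f, bounds=(_MIN_BL, _MAX_BL), method="bounded",
                options={"xatol": brent_xatol})
            if -res.fun >= cur:
                lengths[e] = float(res.x)
                cur = -res.fun
        if cur - prev < tol:
            break
    else:
        warnings.warn("branch-length optimization: no convergence within "
                      f"{max_rounds} rounds; returning best so far")
    itree.lengths = lengths
    return itree.to_tree(), cur


# ---------------------------------------------------------------------------
# per-site rates on a chronogram
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SiteRateVector:
    """Per-site ML rates (substitutions per site per unit tree time)."""

    rates: np.ndarray
    r_max: float

    def __len__(self) -> int:
        return len(self.rates)


def per_site_rates(alignment: Alignment, chronogram: dendropy.Tree,
                   model: SubstitutionModel | None = None,
                   r_max_per_depth: float = 20.0, n_grid: int = 48,
                   tol: float = 1e-8) -> SiteRateVector:
    """ML rate multiplier per site, scaling every branch duration.

    The chronogram is pruned to the alignment's taxa if needed.  The rate
    is bounded by ``r_max_per_depth`` substitutions/site per tree depth;
    invariant sites get rate zero.  Optimization is a vectorized coarse
    grid over log-rate followed by bounded Brent refinement per unique
    site pattern.
    """
    if model is None:
        model = SubstitutionModel.jc()
    leaves = phylo_core.leaf_labels(chronogram)
    taxa = set(alignment.taxa)
    if leaves - taxa:
        chronogram = phylo_core.prune_to_taxa(chronogram, leaves & taxa)
        leaves = phylo_core.leaf_labels(chronogram)
    aln = alignment.subset_taxa([t for t in alignment.taxa if t in leaves])

    depth = max(phylo_core.root_to_tip_distances(chronogram).values())
    r_max = r_max_per_depth / depth

    itree = _prepare(aln, chronogram)
    patt, counts, inverse = compress_patterns(aln)
    tips = encode_tips(patt, model.states)
    itree._tip_rows = {lab: patt.taxa.index(lab) for lab in leaves}
    durations = itree.lengths.copy()

    obs = patt.observed_mask()
    variable = np.zeros(patt.n_sites, dtype=bool)
    for j in range(patt.n_sites):
        states = set(patt.matrix[obs[:, j], j])
        variable[j] = len(states) >= 2

    best = np.zeros(patt.n_sites)
    if variable.any():
        grid = np.concatenate([[r_max * 1e-7],
                               np.geomspace(r_max * 1e-5, r_max, n_grid)])
        ll = np.empty((len(grid), patt.n_sites))
        for gi, r in enumerate(grid):
            ll[gi] = _site_logliks(itree, tips, model, durations * r)
        arg = ll.argmax(axis=0)
        for j in np.where(variable)[0]:
            gi = arg[j]
            lo = grid[max(gi - 1, 0)]
            hi = grid[min(gi + 1, len(grid) - 1)]
            if gi == len(grid) - 1:
                best[j] = r_max if lo >= r_max else _brent_site(
                    itree, tips[:, j:j + 1], model, durations, lo, r_max, tol)
            elif gi == 0:
                best[j] = _brent_site(itree, tips[:, j:j + 1], model,
                                      durations, grid[0], hi, tol)
            else:
                best[j] = _brent_site(itree, tips[:, j:j + 1], model,
                                      durations, lo, hi, tol)
    return SiteRateVector(best[inverse], r_max=r_max)


def _brent_site(itree, tip_col, model, durations, lo, hi, tol) -> float:
    def f(r: float) -> float:
        return -float(_site_logliks(itree, tip_col, model, durations * r)[0])

    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    return float(res.x)


# ---------------------------------------------------------------------------
# constrained topology classes
# ---------------------------------------------------------------------------

def graft_backbone(backbone, clade_subtrees: Mapping[str, str],
                   outgroup_newick: str | None = None,
                   default_length: float = 0.05) -> dendropy.Tree:
    """Expand a clade-level backbone into a terminal-level tree.

    ``clade_subtrees`` maps clade labels to newick subtree strings (with or
    without branch lengths).  Missing lengths default to ``default_length``.
    """

    def expand(node) -> str:
        if isinstance(node, str):
            sub = clade_subtrees[node].rstrip(";")
            return sub
        return f"({expand(node[0])},{expand(node[1])})"

    core = expand(backbone.structure)
    if outgroup_newick is not None:
        core = f"({core},{outgroup_newick.rstrip(';')})"
    tree = phylo_core.parse_tree(core + ";")
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node and (node.edge.length is None or
                                           node.edge.length <= 0):
            node.edge.length = default_length
    return tree


def best_tree_in_class(alignment: Alignment,
                       backbone_class: Sequence,
                       clade_subtrees: Mapping[str, str],
                       model: SubstitutionModel,
                       outgroup_newick: str | None = None,
                       screen_top: int = 3,
                       **optimize_kwargs) -> tuple[dendropy.Tree, float]:
    """Highest-likelihood tree within a constrained backbone class.

    Every backbone is expanded with the fixed within-clade subtrees and
    scored at fixed starting branch lengths; the ``screen_top`` best are
    then branch-length optimized and the class maximum returned.
    """
    if not backbone_class:
        raise ValueError("empty backbone class")
    scored = []
    for bb in backbone_class:
        tree = graft_backbone(bb, clade_subtrees, outgroup_newick)
        scored.append((total_log_likelihood(alignment, tree, model), tree))
    scored.sort(key=lambda p: -p[0])
    best_tree, best_ll = None, -math.inf
    for _, tree in scored[:max(1, screen_top)]:
        opt_tree, ll = optimize_branch_lengths(alignment, tree, model,
                                               **optimize_kwargs)
        if ll > best_ll:
            best_tree, best_ll = opt_tree, ll
    return best_tree, best_ll


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def empirical_frequencies(alignment: Alignment) -> np.ndarray:
    counts = np.array([(alignment.matrix == s).sum() for s in DNA_ALPHABET],
                      dtype=float)
    counts += 1.0  # avoid zeros
    return counts / counts.sum()


_MODEL_MENU = ("JC", "HKY", "GTR")
_EXTRA_MENU = ("G", "GI")


def select_model(alignment: Alignment, tree: dendropy.Tree,
                 gamma_shape: float = 0.5, prop_invariant: float = 0.1,
                 ) -> tuple[str, SubstitutionModel, float]:
    """BIC choice over {JC, HKY, GTR} x {+G, +G+I} with fixed nuisance
    parameters per menu entry (empirical frequencies; kappa and GTR
    exchangeabilities fitted by a short bounded search)."""
    n = alignment.n_sites
    freqs = empirical_frequencies(alignment)
    best = None
    for name in _MODEL_MENU:
        for extra in _EXTRA_MENU:
            gs = gamma_shape
            pi_ = prop_invariant if extra == "GI" else None
            if name == "JC":
                model = SubstitutionModel.jc(gs, pi_)
            elif name == "HKY":
                kappa = _fit_kappa(alignment, tree, freqs, gs, pi_)
                model = SubstitutionModel.hky(kappa, freqs, gs, pi_)
            else:
                model = SubstitutionModel.gtr(
                    _fit_gtr(alignment, tree, freqs, gs, pi_), freqs, gs, pi_)
            _, ll = optimize_branch_lengths(alignment, tree, model,
                                            max_rounds=2)
            n_par = model.n_free_parameters + len(list(
                tree.preorder_node_iter())) - 1
            bic = -2 * ll + n_par * math.log(n)
            if best is None or bic < best[2]:
                best = (f"{name}+{'+'.join(extra)}", model, bic)
    return best


def _fit_kappa(alignment, tree, freqs, gs, pi_) -> float:
    def f(logk):
        m = SubstitutionModel.hky(math.exp(logk), freqs, gs, pi_)
        return -total_log_likelihood(alignment, tree, m)

    res = optimize.minimize_scalar(f, bounds=(math.log(0.2), math.log(50)),
                                   method="bounded", options={"xatol": 1e-3})
    return math.exp(res.x)


def _fit_gtr(alignment, tree, freqs, gs, pi_) -> np.ndarray:
    def f(logex):
        ex = np.concatenate([np.exp(logex), [1.0]])
        m = SubstitutionModel.gtr(ex, freqs, gs, pi_)
        return -total_log_likelihood(alignment, tree, m)

    x0 = np.zeros(5)
    res = optimize.minimize(f, x0, method="L-BFGS-B",
                            bounds=[(-3, 3)] * 5,
                            options={"maxiter": 25, "ftol": 1e-6})
    return np.concatenate([np.exp(res.x), [1.0]])


def export_site_likelihoods(tables: Iterable[SiteLikelihoodTable], path) -> None:
    """Per-site TSV (site, tree_id, lnL), one row per site per tree."""
    import pandas as pd

    rows = []
    for t in tables:
        for j, v in enumerate(t.log_likelihoods):
            rows.append((t.gene, j, t.tree_id, v))
    pd.DataFrame(rows, columns=["gene", "site", "tree_id", "lnL"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
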