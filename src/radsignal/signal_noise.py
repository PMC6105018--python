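"""Phylogenetic informativeness and quartet internode signal/noise.

Two complementary per-site diagnostics of a character's power to resolve a
short internode deep in time:

* **Informativeness profiles.**  A site evolving at rate lambda contributes
  ``rho(t; lambda) = 16 * lambda * t * exp(-4 * lambda * t)`` to the
  dataset profile at time t.  The profile peaks at t = 1/(4 lambda) and,
  at a fixed target depth t, is maximized by the optimal rate
  lambda = 1/(4t): faster sites are informative only for shallow nodes
  because later substitutions overwrite the record.

* **Quartet resolution probabilities.**  For the quartet flanking one
  backbone internode (internode duration t0, four subtending branch
  depths T1..T4) and a gene's per-site rates, sites produce
  parsimony-informative patterns supporting the true resolution or either
  of the two incorrect ones.  Aggregating over the gene's sites gives the
  probability that the gene resolves the internode correctly (QIRP),
  incorrectly via homoplasy (QIHP, both wrong quartets pooled), or not at
  all (QIPP, ties and absence of signal); the three sum to one.

Pattern probabilities are computed exactly from the k-state symmetric
substitution process on the five-branch quartet tree; the distribution of
winning counts over sites is evaluated by seeded Monte Carlo over the
exact per-site category probabilities.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .likelihood import SubstitutionModel


# ---------------------------------------------------------------------------
# informativeness profiles
# ---------------------------------------------------------------------------

def site_informativeness(rate: float, times: np.ndarray) -> np.ndarray:
    """rho(t) = 16 * lambda * t * exp(-4 * lambda * t) for one site."""
    times = np.asarray(times, dtype=float)
    return 16.0 * rate * times * np.exp(-4.0 * rate * times)


def optimal_rate(time: float) -> float:
    """Rate maximizing informativeness at depth ``time``: 1/(4t)."""
    if time <= 0:
        raise ValueError("time must be positive")
    return 1.0 / (4.0 * time)


@dataclasses.dataclass
class PIProfile:
    """Dataset informativeness over a time grid."""

    times: np.ndarray
    informativeness: np.ndarray
    peak_time: float | None

    def standardized(self) -> "PIProfile":
        """Height-standardized copy (peak = 1), for shape comparison."""
        peak = self.informativeness.max()
        scaled = self.informativeness / peak if peak > 0 else self.informativeness
        return PIProfile(self.times, scaled, self.peak_time)


def pi_profile(rates: Sequence[float], time_grid: Sequence[float]) -> PIProfile:
    """Summed informativeness profile of a set of per-site rates.

    All-zero rates yield a flat zero profile with undefined (None) peak.
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(time_grid, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    if len(times) < 2 or (np.diff(times) <= 0).any() or times[0] < 0:
        raise ValueError("time grid must increase from >=0")
    prof = (16.0 * rates[:, None] * times[None, :]
            * np.exp(-4.0 * np.outer(rates, times))).sum(axis=0)
    peak = float(times[int(prof.argmax())]) if prof.max() > 0 else None
    return PIProfile(times, prof, peak)


# ---------------------------------------------------------------------------
# quartet signal and noise
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QuartetGeometry:
    """Five-branch quartet around one internode, in time units.

    ``t0`` is the internode duration; ``subtending`` the four depths from
    the internode's ends to the tips (two on each side).
    """

    t0: float
    subtending: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.t0 < 0 or any(t <= 0 for t in self.subtending):
            raise ValueError("branch durations must be positive "
                             "(internode may be zero)")


@dataclasses.dataclass
class QuartetSignal:
    """Resolution probabilities for one (gene, internode) pair."""

    qirp: float
    qihp: float
    qipp: float
    gene: str = ""
    internode: str = ""

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.qirp, self.qihp, self.qipp)


def site_pattern_probabilities(rate: float, geometry: QuartetGeometry,
                               n_states: int = 4) -> np.ndarray:
    """Exact (P_correct, P_wrong1, P_wrong2) for a single site.

    Tips 1,2 subtend one end of the internode and tips 3,4 the other; a
    parsimony-informative pattern xxyy supports the true topology while
    xyxy / xyyx support the two incorrect resolutions.  Probabilities are
    summed over the internal states of the symmetric k-state process.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    k = n_states
    if rate == 0.0:
        return np.zeros(3)
    model = SubstitutionModel.mk(k)
    T1, T2, T3, T4 = geometry.subtending
    P0 = model.transition_matrices(np.array([rate * geometry.t0]))[0]
    P = [model.transition_matrices(np.array([rate * t]))[0]
         for t in (T1, T2, T3, T4)]
    pi = np.full(k, 1.0 / k)

    # joint tip-state tensor J[a,b,c,d] = P(tips 1..4 = a,b,c,d)
    # internal nodes u (ancestor of 1,2) and v (ancestor of 3,4)
    # P(u)=pi, P(v|u)=P0
    J = np.einsum("u,uv,ua,ub,vc,vd->abcd", pi, P0, P[0], P[1], P[2], P[3])
    idx = np.arange(k)
    a, b, c, d = np.ix_(idx, idx, idx, idx)
    p_true = float((J * ((a == b) & (c == d) & (a != c))).sum())
    p_w1 = float((J * ((a == c) & (b == d) & (a != b))).sum())
    p_w2 = float((J * ((a == d) & (b == c) & (a != b))).sum())
    return np.array([p_true, p_w1, p_w2])


def quartet_probabilities(rates: Sequence[float], geometry: QuartetGeometry,
                          n_states: int = 4, replicates: int = 5000,
                          seed: int | np.random.Generator = 0,
                          gene: str = "", internode: str = "") -> QuartetSignal:
    """QIRP / QIHP / QIPP for a gene's sites on one internode.

    Per-site support-pattern probabilities are exact; the gene-level
    winner distribution (most supporting sites wins; ties -> polytomy) is
    estimated by seeded Monte Carlo over site categories.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    uniq, counts = np.unique(rates, return_counts=True)
    probs = np.array([site_pattern_probabilities(r, geometry, n_states)
                      for r in uniq])  # (uniq, 3)
    if probs.sum() == 0.0:
        return QuartetSignal(0.0, 0.0, 1.0, gene, internode)
    # per replicate: trinomial counts per rate class, summed
    totals = np.zeros((replicates, 3), dtype=np.int64)
    for p, m in zip(probs, counts):
        p4 = np.append(p, max(0.0, 1.0 - p.sum()))
        totals += rng.multinomial(int(m), p4, size=replicates)[:, :3]
    correct, w1, w2 = totals[:, 0], totals[:, 1], totals[:, 2]
    # a resolution wins only with a strictly unique maximum; any tie at the
    # top (including between the two wrong quartets) counts as a polytomy
    qirp = float(np.mean((correct > w1) & (correct > w2)))
    qihp = float(np.mean(((w1 > correct) & (w1 > w2)) |
                         ((w2 > correct) & (w2 > w1))))
    qipp = 1.0 - qirp - qihp
    return QuartetSignal(qirp, qihp, qipp, gene, internode)


def joint_signal_probability(per_internode_qirp: Sequence[float]) -> float:
    """Probability that several internodes are simultaneously resolved
    correctly, under independence: the product of the per-internode QIRP.
    An empty sequence gives 1 (vacuous)."""
    out = 1.0
    for p in per_internode_qirp:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        out *= p
    return out


@dataclasses.dataclass
class ExcessSummary:
    internode: str
    mean_qirp: float
    mean_qihp: float
    excess: float  # mean QIHP / mean QIRP - 1; inf when mean QIRP == 0


def qirp_qihp_excess(signals: Sequence[QuartetSignal]) -> list[ExcessSummary]:
    """Per-internode mean QIRP/QIHP and the incorrect-over-correct excess
    ratio mean(QIHP)/mean(QIRP) - 1 across genes."""
    if not signals:
        raise ValueError("no signals")
    by_internode: dict[str, list[QuartetSignal]] = {}
    for s in signals:
        by_internode.setdefault(s.internode, []).append(s)
    out = []
    for internode, group in by_internode.items():
        mr = float(np.mean([s.qirp for s in group]))
        mh = float(np.mean([s.qihp for s in group]))
        excess = mh / mr - 1.0 if mr > 0 else float("inf")
        out.append(ExcessSummary(internode, mr, mh, excess))
    return out


def backbone_quartet_geometries(chronogram, clade_map,
                                backbone=None) -> dict[str, QuartetGeometry]:
    """Quartet geometry of each backbone internode of a chronogram.

    The chronogram's clade-level backbone is reduced with
    :func:`radsignal.backbone_space.backbone_of`; each internal edge of the
    reduced tree defines an internode whose four flanking clades are
    represented by their earliest-diverging sampled terminal, and branch
    durations are read off the chronogram's node depths.
    """
    from . import backbone_space, phylo_core

    bb, problems = backbone_space.backbone_of(chronogram, clade_map)
    if bb is None:
        raise ValueError(f"chronogram backbone unresolved: {problems}")
    depths = _node_depths(chronogram)
    r2t = phylo_core.root_to_tip_distances(chronogram)
    height = max(r2t.values())

    def clade_age(members: frozenset[str]) -> float:
        mrca = chronogram.mrca(taxon_labels=sorted(members))
        return height - depths[id(mrca)]

    out: dict[str, QuartetGeometry] = {}
    structure = bb.structure
    # walk internal edges of the rooted backbone: each internal non-root
    # node with internal parent defines an internode
    edges = _internal_edges(structure)
    for i, (parent_sets, child) in enumerate(edges):
        child_set = frozenset(_flatten(child))
        sisters = parent_sets - child_set
        top_members = frozenset().union(*[clade_map.members(c) for c in child_set])
        bot_members = frozenset().union(*[clade_map.members(c) for c in sisters])
        t_child = clade_age(top_members)
        t_parent = clade_age(top_members | bot_members)
        t0 = max(t_parent - t_child, 0.0)
        # subtending lineages run from the internode's two ends to the
        # present: two at the child end, two at the parent end
        sub = (t_child, t_child, t_parent, t_parent)
        out[f"internode_{i + 1}_" + "+".join(sorted(child_set))] = \
            QuartetGeometry(t0, sub)
    return out


def _flatten(node):
    if isinstance(node, str):
        return [node]
    return _flatten(node[0]) + _flatten(node[1])


def _internal_edges(structure):
    """(parent leafset, child subtree) for internal non-root children."""
    out = []

    def walk(node):
        if isinstance(node, str):
            return
        pset = frozenset(_flatten(node))
        for ch in node:
            if not isinstance(ch, str):
                out.append((pset, ch))
                walk(ch)

    walk(structure)
    return out


def _node_depths(tree) -> dict[int, float]:
    depths = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[id(node)] = depths[id(node.parent_node)] + (node.edge.length or 0.0)
    return depths
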