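"""Exhaustive enumeration and classification of backbone topologies.

A *backbone topology* is a rooted binary tree whose leaves are the ingroup
clade labels of a radiation (the outgroup is implied to attach below the
root).  With the major clades each constrained monophyletic, the hypothesis
space for the deep structure of the radiation is the set of all rooted
binary trees on the clade labels: (2n-3)!! of them for n labels — 945 for
the six squamate backbone clades.

Named hypotheses are monophyly statements over clade labels.  The two that
dominate the squamate literature are

* Scleroglossa — Iguania sister to all remaining squamates, i.e. the five
  non-Iguania clades form a clade (the morphological signal);
* Toxicofera — Iguania grouped with Anguimorpha and Serpentes (the
  molecular signal).

With six clades the 945 resolutions partition into 105 Scleroglossa,
45 Toxicofera, and 795 rejecting both.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Iterable, Sequence

import dendropy

from . import phylo_core

#: the six squamate backbone clades, in conventional order
SQUAMATE_CLADES: tuple[str, ...] = (
    "Iguania", "Gekkota", "Scincoidea", "Lacertoidea", "Anguimorpha",
    "Serpentes",
)

SCLEROGLOSSA = frozenset(SQUAMATE_CLADES) - {"Iguania"}
TOXICOFERA = frozenset({"Iguania", "Anguimorpha", "Serpentes"})

#: default hypothesis configuration, in priority order
DEFAULT_HYPOTHESES: dict[str, frozenset[str]] = {
    "Scleroglossa": SCLEROGLOSSA,
    "Toxicofera": TOXICOFERA,
}

NEITHER = "neither"

_MAX_LABELS = 9


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! rooted binary trees on n labeled leaves."""
    return double_factorial(2 * n - 3)


# nested-tuple representation: a leaf is a str, an internal node a 2-tuple
_NodeT = object


@dataclasses.dataclass(frozen=True)
class BackboneTopology:
    """Rooted binary tree on clade labels, stored as nested 2-tuples."""

    structure: tuple | str

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(_leaves(self.structure))

    def clade_sets(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes, root included."""
        out: set[frozenset[str]] = set()
        _collect_clades(self.structure, out)
        return out

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        taxa = frozenset(taxa)
        unknown = taxa - self.labels
        if unknown:
            raise KeyError(f"unknown clade labels: {sorted(unknown)}")
        return len(taxa) == 1 or taxa in self.clade_sets()

    def newick(self) -> str:
        return _newick(self.structure) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        t = phylo_core.parse_tree(self.newick())
        t.is_rooted = True
        return t

    def canonical(self) -> tuple | str:
        return _canonical(self.structure)

    def __eq__(self, other) -> bool:  # topology identity, not tuple identity
        return isinstance(other, BackboneTopology) and \
            self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _leaves(node[0]) + _leaves(node[1])


def _collect_clades(node, out: set) -> frozenset[str]:
    if isinstance(node, str):
        return frozenset([node])
    s = _collect_clades(node[0], out) | _collect_clades(node[1], out)
    out.add(s)
    return s


def _newick(node) -> str:
    if isinstance(node, str):
        return node
    return f"({_newick(node[0])},{_newick(node[1])})"


def _canonical(node):
    if isinstance(node, str):
        return node
    kids = sorted((_canonical(node[0]), _canonical(node[1])), key=repr)
    return tuple(kids)


def enumerate_backbones(clade_labels: Sequence[str]) -> list[BackboneTopology]:
    """All rooted binary topologies on ``clade_labels``.

    Enumeration is by recursive insertion of each successive label into
    every branch (including the root branch) of every smaller tree, which
    yields each topology exactly once.
    """
    labels = list(clade_labels)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("clade labels must be unique")
    if not 3 <= n <= _MAX_LABELS:
        raise ValueError(
            f"need 3..{_MAX_LABELS} labels (got {n}; {n} labels would give "
            f"{n_rooted_topologies(n)} topologies)")
    trees: list = [(labels[0], labels[1])]
    for lab in labels[2:]:
        trees = [t2 for t in trees for t2 in _insert_everywhere(t, lab)]
    return [BackboneTopology(t) for t in trees]


def _insert_everywhere(node, lab):
    # attach above the whole subtree...
    yield (node, lab)
    # ...or recursively inside either child
    if not isinstance(node, str):
        for left2 in _insert_everywhere(node[0], lab):
            yield (left2, node[1])
        for right2 in _insert_everywhere(node[1], lab):
            yield (node[0], right2)


def check_hypotheses_exclusive(hypotheses: dict[str, frozenset[str]],
                               clade_labels: Sequence[str]) -> bool:
    """True iff no topology can satisfy two hypotheses at once.

    Verified by brute force over the full enumeration (cheap at backbone
    scale); used at configuration time.
    """
    for topo in enumerate_backbones(list(clade_labels)):
        hits = [h for h, taxa in hypotheses.items() if topo.is_monophyletic(taxa)]
        if len(hits) > 1:
            return False
    return True


def classify_backbone(topology: BackboneTopology,
                      hypotheses: dict[str, frozenset[str]] | None = None) -> str:
    """Name of the first hypothesis whose clade is monophyletic, else
    ``"neither"``.  Warns if several hypotheses are jointly satisfied."""
    if hypotheses is None:
        hypotheses = DEFAULT_HYPOTHESES
    for name, taxa in hypotheses.items():
        if not 2 <= len(taxa) < len(topology.labels):
            raise ValueError(f"hypothesis {name!r} must be a proper subset "
                             "of the clade labels with >=2 members")
    hits = [name for name, taxa in hypotheses.items()
            if topology.is_monophyletic(taxa)]
    if len(hits) > 1:
        warnings.warn(f"topology satisfies several hypotheses: {hits}; "
                      "returning the first in configuration order")
    return hits[0] if hits else NEITHER


def classify_all(clade_labels: Sequence[str] = SQUAMATE_CLADES,
                 hypotheses: dict[str, frozenset[str]] | None = None,
                 ) -> Counter:
    """Partition the full enumeration into hypothesis classes."""
    if hypotheses is None:
        hypotheses = DEFAULT_HYPOTHESES
    counts: Counter = Counter()
    for topo in enumerate_backbones(list(clade_labels)):
        counts[classify_backbone(topo, hypotheses)] += 1
    return counts


def backbones_by_class(clade_labels: Sequence[str] = SQUAMATE_CLADES,
                       hypotheses: dict[str, frozenset[str]] | None = None,
                       ) -> dict[str, list[BackboneTopology]]:
    if hypotheses is None:
        hypotheses = DEFAULT_HYPOTHESES
    out: dict[str, list[BackboneTopology]] = {}
    for topo in enumerate_backbones(list(clade_labels)):
        out.setdefault(classify_backbone(topo, hypotheses), []).append(topo)
    return out


def backbone_of(tree: dendropy.Tree, clade_map: phylo_core.CladeMap,
                ) -> tuple[BackboneTopology | None, list[str]]:
    """Reduce a terminal-level tree to its clade backbone.

    Returns ``(backbone, problems)``.  ``backbone`` is None when any sampled
    ingroup clade is non-monophyletic; ``problems`` then lists those clades.
    Clades with no sampled terminal are excluded and flagged with a
    ``"<clade>:unsampled"`` entry.
    """
    leaves = phylo_core.leaf_labels(tree)
    problems: list[str] = []
    sampled: dict[str, frozenset[str]] = {}
    for clade in clade_map.clade_labels:
        members = clade_map.members(clade) & leaves
        if not members:
            problems.append(f"{clade}:unsampled")
            continue
        sampled[clade] = members
    nonmono = [c for c, m in sampled.items()
               if not phylo_core.is_monophyletic(tree, m)]
    if nonmono:
        return None, problems + nonmono

    # one representative per clade, plus an outgroup terminal to root by
    reps = {min(m): c for c, m in sampled.items()}
    og = clade_map.outgroup_terminals & leaves
    keep = set(reps) | (set([min(og)]) if og else set())
    induced = phylo_core.prune_to_taxa(tree, keep)
    if og:
        og_leaf = next(lf for lf in induced.leaf_node_iter()
                       if lf.taxon.label == min(og))
        induced.to_outgroup_position(og_leaf, update_bipartitions=False,
                                     suppress_unifurcations=True)
    structure = _structure_from_node(induced.seed_node, reps, min(og) if og else None)
    return BackboneTopology(structure), problems


def _structure_from_node(node, reps: dict[str, str], outgroup: str | None):
    def build(nd):
        if nd.is_leaf():
            return reps[nd.taxon.label]
        kids = [build(ch) for ch in nd.child_nodes()]
        out = kids[0]
        for k in kids[1:]:  # polytomies cannot arise here, but be safe
            out = (out, k)
        return out

    kids = node.child_nodes()
    subtrees = []
    for ch in kids:
        labels = {lf.taxon.label for lf in ch.leaf_iter()}
        if outgroup is not None and labels == {outgroup}:
            continue
        subtrees.append(build(ch))
    out = subtrees[0]
    for s in subtrees[1:]:
        out = (out, s)
    return out


def classification_table(clade_labels: Sequence[str] = SQUAMATE_CLADES,
                         hypotheses: dict[str, frozenset[str]] | None = None):
    """(newick, class) rows for the full enumeration, as a DataFrame."""
    import pandas as pd

    if hypotheses is None:
        hypotheses = DEFAULT_HYPOTHESES
    rows = [(t.newick(), classify_backbone(t, hypotheses))
            for t in enumerate_backbones(list(clade_labels))]
    return pd.DataFrame(rows, columns=["topology", "hypothesis"])
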