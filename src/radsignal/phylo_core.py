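"""Tree and alignment containers plus the comparison primitives everything
else builds on.

Trees are plain :class:`dendropy.Tree` objects throughout the package; this
module adds split extraction, Robinson-Foulds distances with shared-leaf
pruning, monophyly tests, and root-to-tip path lengths, together with
readers/writers for the standard text formats (newick, NEXUS, FASTA,
relaxed PHYLIP).

Conventions
-----------
* Tree comparisons (RF, monophyly) use the *unrooted* view by default:
  gene trees inferred without an outgroup constraint carry no meaningful
  root.  Rooted clade tests are available via ``rooted=True``.
* A bipartition ("split") is stored canonically as the side *not*
  containing the lexicographically smallest leaf label, so a split and its
  complement compare equal.
* Zero-length and unresolved branches are kept as polytomies; polytomous
  trees simply contribute fewer nontrivial splits.
* Leaf-name matching is exact; :func:`normalize_label` is an optional hook
  for underscore/space normalization and is off by default.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Nexus import Nexus

DNA_ALPHABET = "ACGT"
#: characters treated as "no observation" in a DNA column
DNA_MISSING = frozenset("-?NnXx.~")
#: IUPAC ambiguity codes -> compatible nucleotide states
DNA_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


class TreeParseError(ValueError):
    """Malformed tree input (unbalanced parentheses, duplicate labels...)."""


class UndefinedDistanceError(ValueError):
    """Raised when two trees share fewer than four leaves."""


def normalize_label(label: str) -> str:
    """Default normalization hook: underscores to spaces, trimmed."""
    return label.replace("_", " ").strip()


# ---------------------------------------------------------------------------
# tree I/O
# ---------------------------------------------------------------------------

def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a single newick string into a tree, with duplicate-label check."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"cannot parse newick: {exc}") from exc
    _check_unique_leaves(tree)
    return tree


def read_tree(path, schema: str = "newick") -> dendropy.Tree:
    """Read the first tree in ``path`` (newick or nexus)."""
    _check_schema(schema)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(f"{path}: {exc}") from exc
    _check_unique_leaves(tree)
    return tree


def read_trees(path, schema: str = "newick") -> list[dendropy.Tree]:
    """Read every tree in a file; NEXUS translate tables are honored."""
    _check_schema(schema)
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema=schema, preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeParseError(f"{path}: {exc}") from exc
    out = list(trees)
    for t in out:
        _check_unique_leaves(t)
    return out


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with >=10 significant digits on branch lengths."""
    return tree.as_string(
        schema="newick", real_value_format_specifier=".12g",
        suppress_rooting=True, unquoted_underscores=True,
    ).strip()


def write_tree(tree: dendropy.Tree, path, schema: str = "newick") -> None:
    _check_schema(schema)
    tree.write(
        path=str(path), schema=schema, real_value_format_specifier=".12g",
        suppress_rooting=(schema == "newick"), unquoted_underscores=True,
    )


def _check_schema(schema: str) -> None:
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {schema!r}")


def _check_unique_leaves(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeParseError(f"duplicate leaf labels: {dupes}")


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def is_binary(tree: dendropy.Tree, rooted: bool | None = None) -> bool:
    """Binary check: every internal node has exactly two children (rooted
    view) or, for the unrooted view, the root may have three."""
    if rooted is None:
        rooted = bool(tree.is_rooted)
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if nch == 0:
            continue
        if node is tree.seed_node and not rooted:
            if nch not in (2, 3):
                return False
        elif nch != 2:
            return False
    return True


# ---------------------------------------------------------------------------
# splits / RF / monophyly
# ---------------------------------------------------------------------------

def canonical_split(side: Iterable[str], universe: frozenset[str]) -> frozenset[str]:
    """Canonical orientation: the side not containing min(universe)."""
    side = frozenset(side)
    ref = min(universe)
    return universe - side if ref in side else side


def nontrivial_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the unrooted view of ``tree``.

    Each split is the canonical side (see :func:`canonical_split`).  Trees
    with three or fewer leaves, and star trees, yield the empty set.
    """
    universe = leaf_labels(tree)
    n = len(universe)
    splits: set[frozenset[str]] = set()
    if n < 4:
        return splits
    # leaf set under each non-root node == one side of the edge above it
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = acc
        if node is not tree.seed_node:
            side = below[id(node)]
            if 2 <= len(side) <= n - 2:
                splits.add(canonical_split(side, universe))
    return splits


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced tree on ``taxa`` (a deep copy; original untouched)."""
    taxa = set(taxa)
    pruned = tree.extract_tree_with_taxa_labels(labels=taxa)
    return pruned


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree,
                normalized: bool = True) -> float:
    """Robinson-Foulds distance after pruning both trees to shared leaves.

    The normalized form is the number of bipartitions unique to either tree
    divided by the total number of bipartitions in both, as used when
    comparing gene trees with unequal taxon sampling.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    shared = l1 & l2
    if len(shared) < 4:
        raise UndefinedDistanceError(
            f"only {len(shared)} shared leaves; need >=4")
    if shared != l1:
        t1 = prune_to_taxa(t1, shared)
    if shared != l2:
        t2 = prune_to_taxa(t2, shared)
    s1, s2 = nontrivial_splits(t1), nontrivial_splits(t2)
    d = len(s1 ^ s2)
    if not normalized:
        return float(d)
    denom = len(s1) + len(s2)
    return d / denom if denom else 0.0


def is_monophyletic(tree: dendropy.Tree, taxon_set: Iterable[str],
                    rooted: bool = False) -> bool:
    """Monophyly test.

    Unrooted (default): the set is one side of some split, or trivial
    (singleton, complement-singleton, or the full leaf set).  Rooted: some
    node's descendant leaf set equals the set exactly.
    """
    taxon_set = frozenset(taxon_set)
    universe = leaf_labels(tree)
    unknown = taxon_set - universe
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    n = len(universe)
    if rooted:
        if len(taxon_set) == 1 or taxon_set == universe:
            return True
        for node in tree.postorder_internal_node_iter():
            if frozenset(lf.taxon.label for lf in node.leaf_iter()) == taxon_set:
                return True
        return False
    if len(taxon_set) in (1, n - 1, n):
        return True
    return canonical_split(taxon_set, universe) in nontrivial_splits(tree)


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to every terminal."""
    dist: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has missing branch lengths")
        dist[id(node)] = dist[id(node.parent_node)] + node.edge.length
        if node.is_leaf():
            out[node.taxon.label] = dist[id(node)]
    return out


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    d = list(root_to_tip_distances(tree).values())
    return max(d) - min(d) <= tol * max(max(d), 1.0)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Alignment:
    """Taxa x sites character matrix.

    ``matrix`` holds single-character state codes (uppercase for DNA).
    ``partition_map`` maps gene names to arrays of 0-based site indices;
    blocks must be disjoint and cover the alignment when present.
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str = DNA_ALPHABET
    partition_map: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (taxa x sites)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise ValueError("taxa list does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.partition_map is not None:
            self.partition_map = {
                g: np.asarray(ix, dtype=int) for g, ix in self.partition_map.items()
            }
            allix = np.concatenate(list(self.partition_map.values())) if \
                self.partition_map else np.empty(0, int)
            if len(np.unique(allix)) != len(allix):
                raise ValueError("partition blocks overlap")
            if len(allix) != self.n_sites or (len(allix) and
                                              (allix.min() < 0 or allix.max() >= self.n_sites)):
                raise ValueError("partition blocks must cover all sites")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.partition_map) if self.partition_map else []

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def column(self, i: int) -> np.ndarray:
        return self.matrix[:, i]

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str], alphabet: str = DNA_ALPHABET,
                  partition_map: dict[str, np.ndarray] | None = None) -> "Alignment":
        taxa = list(seqs)
        mat = np.array([list(seqs[t].upper()) for t in taxa], dtype="<U1")
        return cls(taxa, mat, alphabet, partition_map)

    # -- subsetting --------------------------------------------------------
    def subset_sites(self, indices: Sequence[int]) -> "Alignment":
        indices = np.asarray(indices, dtype=int)
        return Alignment(list(self.taxa), self.matrix[:, indices], self.alphabet)

    def subset_taxa(self, names: Sequence[str]) -> "Alignment":
        rows = [self.taxa.index(t) for t in names]
        pm = None
        if self.partition_map is not None:
            pm = {g: ix.copy() for g, ix in self.partition_map.items()}
        return Alignment(list(names), self.matrix[rows], self.alphabet, pm)

    def gene(self, name: str) -> "Alignment":
        if not self.partition_map or name not in self.partition_map:
            raise KeyError(f"no such gene partition: {name}")
        return self.subset_sites(self.partition_map[name])

    # -- summaries ---------------------------------------------------------
    def observed_mask(self) -> np.ndarray:
        """Boolean (taxa x sites): True where an unambiguous state is coded."""
        obs = np.isin(self.matrix, list(self.alphabet))
        return obs

    def variable_sites(self) -> np.ndarray:
        """Indices of sites with >=2 distinct observed states."""
        obs = self.observed_mask()
        out = []
        for j in range(self.n_sites):
            states = set(self.matrix[obs[:, j], j])
            if len(states) >= 2:
                out.append(j)
        return np.asarray(out, dtype=int)


def contiguous_partition(gene_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Partition map for genes concatenated in order."""
    out, start = {}, 0
    for g, ln in gene_lengths.items():
        out[g] = np.arange(start, start + ln)
        start += ln
    return out


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read FASTA / relaxed PHYLIP / NEXUS alignments.

    NEXUS ``charset`` definitions are mapped onto ``partition_map``.
    """
    path = str(path)
    if format == "fasta":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        if not seqs:
            raise ValueError(f"{path}: no sequences found")
        return Alignment.from_dict(seqs)
    if format == "phylip":
        aln = AlignIO.read(path, "phylip-relaxed")
        return Alignment.from_dict({rec.id: str(rec.seq).upper() for rec in aln})
    if format == "nexus":
        nex = Nexus.Nexus(path)
        seqs = {name: str(seq).upper() for name, seq in nex.matrix.items()}
        pm = None
        if nex.charsets:
            pm = {g: np.asarray(sorted(ix), dtype=int)
                  for g, ix in nex.charsets.items()}
            covered = sorted(set(np.concatenate(list(pm.values())).tolist()))
            if covered != list(range(len(next(iter(seqs.values()))))):
                pm = None  # charsets incomplete -> ignore, keep sequences
        alphabet = DNA_ALPHABET
        if nex.datatype and nex.datatype.lower() in ("standard", "protein"):
            states = sorted({c for s in seqs.values() for c in s
                             if c not in "-?"})
            alphabet = "".join(states)
        return Alignment.from_dict(seqs, alphabet=alphabet, partition_map=pm)
    raise ValueError(f"unsupported alignment format: {format!r}")


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n{aln.sequence(t)}\n")


def write_phylip(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
        width = max(len(t) for t in aln.taxa) + 2
        for t in aln.taxa:
            fh.write(t.ljust(width) + aln.sequence(t) + "\n")


def write_nexus(aln: Alignment, path) -> None:
    dtype = "DNA" if aln.alphabet == DNA_ALPHABET else "STANDARD"
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_sites};\n")
        fh.write(f"  FORMAT DATATYPE={dtype} MISSING=? GAP=-")
        if dtype == "STANDARD":
            fh.write(f' SYMBOLS="{aln.alphabet}"')
        fh.write(";\n  MATRIX\n")
        width = max(len(t) for t in aln.taxa) + 2
        for t in aln.taxa:
            fh.write("    " + t.ljust(width) + aln.sequence(t) + "\n")
        fh.write("  ;\nEND;\n")
        if aln.partition_map:
            fh.write("BEGIN SETS;\n")
            for g, ix in aln.partition_map.items():
                ranges = _index_ranges(np.sort(ix))
                spec = " ".join(f"{a + 1}-{b + 1}" if a != b else f"{a + 1}"
                                for a, b in ranges)
                fh.write(f"  CHARSET {g} = {spec};\n")
            fh.write("END;\n")


def _index_ranges(ix: np.ndarray) -> list[tuple[int, int]]:
    ranges = []
    for v in ix:
        if ranges and v == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], int(v))
        else:
            ranges.append((int(v), int(v)))
    return ranges


# ---------------------------------------------------------------------------
# clade membership
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CladeMap:
    """Assignment of terminals to named backbone clades, plus the outgroup."""

    clade_of: dict[str, str]
    clade_labels: list[str]
    outgroup_label: str

    def __post_init__(self) -> None:
        if self.outgroup_label in self.clade_labels:
            raise ValueError("outgroup label must differ from ingroup labels")
        used = set(self.clade_of.values())
        missing = [c for c in self.clade_labels if c not in used]
        if missing:
            raise ValueError(f"clades with no terminals: {missing}")
        bad = used - set(self.clade_labels) - {self.outgroup_label}
        if bad:
            raise ValueError(f"terminals assigned to unknown clades: {sorted(bad)}")

    def members(self, clade: str) -> frozenset[str]:
        return frozenset(t for t, c in self.clade_of.items() if c == clade)

    @property
    def ingroup_terminals(self) -> frozenset[str]:
        return frozenset(t for t, c in self.clade_of.items()
                         if c != self.outgroup_label)

    @property
    def outgroup_terminals(self) -> frozenset[str]:
        return self.members(self.outgroup_label)

    @classmethod
    def from_tsv(cls, path, outgroup_label: str) -> "CladeMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["terminal", "clade"], dtype=str)
        clade_of = dict(zip(df.terminal, df.clade))
        if len(clade_of) != len(df):
            raise ValueError("terminal mapped more than once")
        labels = [c for c in dict.fromkeys(df.clade) if c != outgroup_label]
        return cls(clade_of, labels, outgroup_label)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"terminal": list(self.clade_of), "clade": list(self.clade_of.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


def write_distance_matrix(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.10g")
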