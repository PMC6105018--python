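"""Synthetic ancient-radiation datasets.

Generates the statistical structure the rest of the pipeline assumes: a
bush-shaped chronogram in which six ingroup clades plus an outgroup
diverge across a handful of very short internodes deep in time, multi-gene
nucleotide alignments evolved along it with lineage-specific rate
multipliers and a nonstationary AT-ward composition shift on two
designated non-sister clades, and (optionally) slowly evolving Mk-type
discrete characters.  The defaults emulate the squamate scenario: a
~190 Ma ingroup crown, backbone internodes of 4.6-8.7 Ma, 46 genes,
a 1.6x rate multiplier and a +1.3 percentage-point AT enrichment on
Iguania and Serpentes.

Everything is seeded: identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import dendropy
import numpy as np

from . import backbone_space, phylo_core
from .likelihood import SubstitutionModel
from .phylo_core import Alignment, CladeMap, contiguous_partition

#: rooted backbones over the six squamate clade labels
BACKBONE_HYP_A = ("Iguania", ("Gekkota", ("Scincoidea", ("Lacertoidea",
                  ("Anguimorpha", "Serpentes")))))
BACKBONE_HYP_B = ("Gekkota", ("Scincoidea", ("Lacertoidea", ("Iguania",
                  ("Anguimorpha", "Serpentes")))))

_DEFAULT_TERMINALS = {
    "Iguania": 12, "Gekkota": 5, "Scincoidea": 6, "Lacertoidea": 6,
    "Anguimorpha": 7, "Serpentes": 9,
}


@dataclasses.dataclass
class RadiationConfig:
    """Study conditions for one synthetic radiation.

    Durations in Ma; rates in substitutions/site/Ma.  ``at_shift`` moves
    that fraction of total base frequency from G+C onto A+T on the
    designated biased clades (from their stem branches tipward), and
    ``at_skew_shift`` tilts their AT pool toward A so the enrichment is
    also visible as an AT-skew signature.
    """

    seed: int
    clade_labels: tuple[str, ...] = backbone_space.SQUAMATE_CLADES
    outgroup_label: str = "Sphenodon"
    terminals_per_clade: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_TERMINALS))
    root_depth: float = 190.0
    outgroup_depth: float = 240.0
    internode_range: tuple[float, float] = (4.6, 8.7)
    true_backbone: str | tuple = "HYP_A"
    crown_fraction_range: tuple[float, float] = (0.55, 0.8)
    n_genes: int = 46
    gene_length_log_mean: float = float(np.log(1000.0))
    gene_length_log_sd: float = 0.45
    gene_length_bounds: tuple[int, int] = (300, 3000)
    base_rate: float = 0.002
    rate_multiplier: float = 1.6
    biased_clades: tuple[str, ...] = ("Iguania", "Serpentes")
    base_frequencies: tuple[float, ...] = (0.28, 0.22, 0.22, 0.28)
    at_shift: float = 0.013
    at_skew_shift: float = 0.25
    kappa: float = 3.0
    gamma_shape: float = 0.8
    prop_invariant: float = 0.2
    missing_fraction: float = 0.10
    n_morph_chars: int = 0
    mk_rate: float = 0.0015
    mk_states: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.rate_multiplier <= 0 or self.base_rate <= 0:
            raise ValueError("rates and multipliers must be positive")
        lo, hi = self.internode_range
        if not 0 < lo <= hi:
            raise ValueError("invalid internode range")
        if (len(self.clade_labels) - 1) * hi >= self.root_depth:
            raise ValueError("backbone internodes exceed the root depth")
        pi = np.asarray(self.base_frequencies)
        at = pi[0] + pi[3]
        if not 0 < at + self.at_shift < 1:
            raise ValueError("AT shift leaves the frequency simplex")
        unknown = set(self.biased_clades) - set(self.clade_labels)
        if unknown:
            raise ValueError(f"biased clades not in clade set: {unknown}")

    def backbone_structure(self) -> tuple:
        if isinstance(self.true_backbone, tuple):
            return self.true_backbone
        return {"HYP_A": BACKBONE_HYP_A, "HYP_B": BACKBONE_HYP_B}[
            self.true_backbone]

    def shifted_frequencies(self) -> tuple[float, ...]:
        """Equilibrium frequencies of the biased lineages.

        AT gains ``at_shift`` at the expense of G+C (pro rata), and the AT
        pool itself is rebalanced toward A by ``at_skew_shift`` (the new
        AT skew, assuming a symmetric baseline) — AT-rich *and* A-skewed,
        the two compositional signatures the diagnostics look for.
        """
        a, c, g, t = self.base_frequencies
        gc = c + g
        at_new = a + t + self.at_shift
        base_skew = (a - t) / (a + t)
        skew = base_skew + self.at_skew_shift
        return (at_new * (1 + skew) / 2.0,
                c - self.at_shift * c / gc,
                g - self.at_shift * g / gc,
                at_new * (1 - skew) / 2.0)

    def clade_map(self) -> CladeMap:
        clade_of = {}
        for clade in self.clade_labels:
            for i in range(self.terminals_per_clade[clade]):
                clade_of[f"{clade}_{i + 1}"] = clade
        clade_of[self.outgroup_label] = self.outgroup_label
        return CladeMap(clade_of, list(self.clade_labels), self.outgroup_label)


# ---------------------------------------------------------------------------
# chronogram + rate tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "age", "label", "rate_mult", "shifted")

    def __init__(self, age: float, label: str | None = None):
        self.children: list[_Node] = []
        self.age = age           # Ma before present
        self.label = label
        self.rate_mult = 1.0
        self.shifted = False


def _yule_clade(labels: Sequence[str], crown_age: float,
                rng: np.random.Generator) -> _Node:
    """Random ultrametric clade: coalescent-style joins at uniform-ordered
    depths below the crown age (a simple Yule-like shape)."""
    nodes = [_Node(0.0, lab) for lab in labels]
    if len(nodes) == 1:
        return nodes[0]
    ages = np.sort(rng.uniform(0.0, 1.0, size=len(nodes) - 1)) * crown_age
    ages[-1] = crown_age  # the clade's crown node sits exactly at crown_age
    for age in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _Node(float(age))
        parent.children = [nodes[i], nodes[j]]
        nodes[j:j + 1] = []
        nodes[i] = parent
    return nodes[0]


def _newick(node: _Node, parent_age: float, lengths_from: str,
            base_rate: float) -> str:
    dur = parent_age - node.age
    if lengths_from == "time":
        bl = dur
    else:
        bl = dur * base_rate * node.rate_mult
    if not node.children:
        return f"{node.label}:{bl:.17g}"
    inner = ",".join(_newick(ch, node.age, lengths_from, base_rate)
                     for ch in node.children)
    return f"({inner}):{bl:.17g}"


def generate_radiation_tree(config: RadiationConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[dendropy.Tree, dendropy.Tree, dict]:
    """Chronogram (Ma) and matching rate tree (expected substitutions).

    The backbone follows ``config.true_backbone`` with internode durations
    drawn uniformly from ``internode_range``; within-clade topologies are
    random ultrametric (Yule-like) shapes; the outgroup attaches below the
    ingroup crown.  Rate multipliers and the AT shift are inherited from
    the stems of the biased clades tipward.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    structure = config.backbone_structure()
    n_intern = len(backbone_space._leaves(structure)) - 1
    draws = rng.uniform(*config.internode_range, size=n_intern)
    ingroup = _build_backbone(structure, config, draws, rng)
    root = _Node(config.outgroup_depth)
    og = _Node(0.0, config.outgroup_label)
    root.children = [ingroup, og]

    _apply_bias(root, config)

    chrono = phylo_core.parse_tree(
        "(" + ",".join(_newick(ch, root.age, "time", 1.0)
                       for ch in root.children) + ");")
    chrono.is_rooted = True
    rate_tree = phylo_core.parse_tree(
        "(" + ",".join(_newick(ch, root.age, "rate", config.base_rate)
                       for ch in root.children) + ");")
    rate_tree.is_rooted = True
    meta = {"internode_draws": draws.tolist(),
            "backbone": repr(structure)}
    return chrono, rate_tree, meta


def _build_backbone(structure, config: RadiationConfig, draws: np.ndarray,
                    rng: np.random.Generator) -> _Node:
    """Recursive backbone construction; clade tips expand to Yule clades."""
    counter = {"i": 0}

    def clade_node(label: str, stem_age: float) -> _Node:
        crown = rng.uniform(*config.crown_fraction_range) * stem_age
        members = [f"{label}_{i + 1}"
                   for i in range(config.terminals_per_clade[label])]
        return _yule_clade(members, crown, rng)

    def walk(node, age: float) -> _Node:
        if isinstance(node, str):
            return clade_node(node, age)
        out = _Node(age)
        for ch in node:
            if isinstance(ch, str):
                out.children.append(clade_node(ch, age))
            else:
                child_age = age - draws[counter["i"]]
                counter["i"] += 1
                out.children.append(walk(ch, child_age))
        return out

    return walk(structure, config.root_depth)


def _apply_bias(root: _Node, config: RadiationConfig) -> None:
    """Set rate multipliers / frequency shift on biased clades (stem down)."""
    biased_prefixes = tuple(f"{c}_" for c in config.biased_clades)

    def leafset(node: _Node) -> set[str]:
        if not node.children:
            return {node.label}
        out: set[str] = set()
        for ch in node.children:
            out |= leafset(ch)
        return out

    def walk(node: _Node, inherited: bool) -> None:
        here = inherited
        if not here:
            ls = leafset(node)
            for clade in config.biased_clades:
                if ls and all(x.startswith(f"{clade}_") for x in ls):
                    here = True
                    break
        if here:
            node.rate_mult = config.rate_multiplier
            node.shifted = True
        for ch in node.children:
            walk(ch, here)

    walk(root, False)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    """One simulated radiation: truth + data + provenance."""

    config: RadiationConfig
    chronogram: dendropy.Tree
    rate_tree: dendropy.Tree
    alignment: Alignment
    site_rates: np.ndarray        # per-site rate multiplier x base rate (per Ma)
    gene_lengths: dict[str, int]
    clade_map: CladeMap
    morphology: Alignment | None = None

    def provenance(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["terminals_per_clade"] = dict(cfg["terminals_per_clade"])
        cfg["true_backbone"] = repr(self.config.true_backbone)
        return {"config": cfg}

    def write(self, directory) -> None:
        import os

        d = str(directory)
        os.makedirs(d, exist_ok=True)
        phylo_core.write_fasta(self.alignment, os.path.join(d, "alignment.fasta"))
        phylo_core.write_nexus(self.alignment, os.path.join(d, "alignment.nex"))
        phylo_core.write_tree(self.chronogram, os.path.join(d, "chronogram.nwk"))
        phylo_core.write_tree(self.rate_tree, os.path.join(d, "rate_tree.nwk"))
        self.clade_map.to_tsv(os.path.join(d, "clade_map.tsv"))
        with open(os.path.join(d, "provenance.json"), "w") as fh:
            json.dump(self.provenance(), fh, indent=1)


def _branch_regimes(chronogram: dendropy.Tree, config: RadiationConfig
                    ) -> dict[int, tuple[float, bool]]:
    """(rate multiplier, shifted?) per node id, stem-inherited."""
    out: dict[int, tuple[float, bool]] = {}

    def clade_of_leafset(ls: frozenset[str]) -> str | None:
        for clade in config.biased_clades:
            if all(x.startswith(f"{clade}_") for x in ls):
                return clade
        return None

    leafsets: dict[int, frozenset[str]] = {}
    for node in chronogram.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for ch in node.child_nodes():
                acc |= leafsets[id(ch)]
            leafsets[id(node)] = acc

    def walk(node, inherited: bool) -> None:
        here = inherited or clade_of_leafset(leafsets[id(node)]) is not None
        mult = config.rate_multiplier if here else 1.0
        out[id(node)] = (mult, here)
        for ch in node.child_nodes():
            walk(ch, here)

    walk(chronogram.seed_node, False)
    return out


def _sample_states(P_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical state per row of a (n, k) probability array."""
    cum = np.cumsum(P_rows, axis=1)
    u = rng.random((P_rows.shape[0], 1))
    return (u > cum[:, :-1]).sum(axis=1)


def simulate_alignment(config: RadiationConfig,
                       chronogram: dendropy.Tree | None = None,
                       rng: np.random.Generator | None = None
                       ) -> SyntheticDataset:
    """Evolve the multi-gene alignment along the radiation.

    Per gene: length ~ clipped log-normal; site-rate multipliers from the
    +I+Gamma mixture; each site evolves root -> tips under an HKY process
    whose equilibrium frequencies switch to the AT-shifted vector on the
    biased clades' stems (nonstationary composition) and whose rate is
    ``base_rate * lineage multiplier * site multiplier``.  Whole genes go
    missing per taxon with probability ``missing_fraction``.
    """
    master = rng if rng is not None else np.random.default_rng(config.seed)
    if chronogram is None:
        chronogram, _, _ = generate_radiation_tree(config, master)
    regimes = _branch_regimes(chronogram, config)

    model_bg = SubstitutionModel.hky(config.kappa,
                                     np.asarray(config.base_frequencies))
    model_sh = SubstitutionModel.hky(config.kappa,
                                     np.asarray(config.shifted_frequencies()))

    nodes = list(chronogram.preorder_node_iter())
    taxa = [lf.taxon.label for lf in chronogram.leaf_node_iter()]

    lengths_raw = np.exp(master.normal(config.gene_length_log_mean,
                                       config.gene_length_log_sd,
                                       size=config.n_genes))
    lo, hi = config.gene_length_bounds
    gene_lengths = {f"gene_{i + 1}": int(np.clip(round(L), lo, hi))
                    for i, L in enumerate(lengths_raw)}

    all_sites: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    site_rate_chunks: list[np.ndarray] = []
    states = np.array(list("ACGT"))

    for gene, L in gene_lengths.items():
        inv = master.random(L) < config.prop_invariant
        gam = master.gamma(config.gamma_shape,
                           1.0 / config.gamma_shape, size=L)
        mult = np.where(inv, 0.0, gam / (1.0 - config.prop_invariant))
        site_rate_chunks.append(mult * config.base_rate)

        seqs: dict[int, np.ndarray] = {}
        root = chronogram.seed_node
        pi0 = np.asarray(config.base_frequencies)
        seqs[id(root)] = _sample_states(np.tile(pi0, (L, 1)), master)
        for node in nodes:
            if node is root:
                continue
            parent_states = seqs[id(node.parent_node)]
            dur = node.edge.length or 0.0
            m, shifted = regimes[id(node)]
            model = model_sh if shifted else model_bg
            bl = dur * config.base_rate * m * mult  # per-site branch lengths
            P = model.transition_matrices(bl)       # (L, 4, 4)
            rows = P[np.arange(L), parent_states]
            seqs[id(node)] = _sample_states(rows, master)
        leaf_by_label = {lf.taxon.label: seqs[id(lf)]
                         for lf in chronogram.leaf_node_iter()}
        for t in taxa:
            missing = master.random() < config.missing_fraction
            if missing:
                all_sites[t].append(np.full(L, "?", dtype="<U1"))
            else:
                all_sites[t].append(states[leaf_by_label[t]])

    matrix = np.vstack([np.concatenate(all_sites[t]) for t in taxa])
    aln = Alignment(taxa, matrix, partition_map=contiguous_partition(gene_lengths))
    rate_tree = _rate_tree_from(chronogram, regimes, config)
    morph = None
    if config.n_morph_chars > 0:
        morph = simulate_morphology(chronogram, config.n_morph_chars,
                                    config.mk_rate, config.mk_states, master)
    return SyntheticDataset(config, chronogram, rate_tree, aln,
                            np.concatenate(site_rate_chunks), gene_lengths,
                            config.clade_map(), morph)


def _rate_tree_from(chronogram, regimes, config) -> dendropy.Tree:
    rate_tree = chronogram.clone(depth=1)
    orig = list(chronogram.preorder_node_iter())
    for node, node0 in zip(rate_tree.preorder_node_iter(), orig):
        if node.edge.length is not None:
            m, _ = regimes[id(node0)]
            node.edge.length = node.edge.length * config.base_rate * m
    return rate_tree


def simulate_morphology(chronogram: dendropy.Tree, n_chars: int,
                        mk_rate: float, n_states: int = 2,
                        rng: np.random.Generator | int = 0) -> Alignment:
    """Mk-type discrete characters on the chronogram (uniform root, one
    shared rate; slow by default so informativeness peaks deeper in time)."""
    if n_states < 2:
        raise ValueError("Mk needs at least two states")
    if mk_rate <= 0:
        raise ValueError("mk_rate must be positive")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    model = SubstitutionModel.mk(n_states)
    nodes = list(chronogram.preorder_node_iter())
    root = chronogram.seed_node
    seqs = {id(root): rng.integers(0, n_states, size=n_chars)}
    for node in nodes:
        if node is root:
            continue
        dur = node.edge.length or 0.0
        P = model.transition_matrices(np.array([dur * mk_rate]))[0]
        rows = P[seqs[id(node.parent_node)]]
        seqs[id(node)] = _sample_states(rows, rng)
    taxa = [lf.taxon.label for lf in chronogram.leaf_node_iter()]
    symbols = np.array(list(model.states))
    matrix = np.vstack([symbols[seqs[id(lf)]]
                        for lf in chronogram.leaf_node_iter()])
    return Alignment(taxa, matrix, alphabet=model.states)
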