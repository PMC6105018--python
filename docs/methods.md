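# Methods

`radsignal` implements a battery of diagnostics for a single question: when
a clade radiated quickly a long time ago, does a multi-gene molecular
dataset actually carry the signal needed to resolve the order of the deep
branching — and if not, which combination of noise and systematic bias is
shaping the tree instead?  The design target is the squamate (lizard)
backbone problem: six major clades diverging across internodes of roughly
4.6–8.7 Ma at ~170–190 Ma depth, with the position of Iguania contested
between a morphological arrangement (Iguania sister to everything else,
"Scleroglossa") and a molecular one (Iguania beside snakes and
anguimorphs, "Toxicofera").

## The constrained hypothesis space

With each major clade held monophyletic, the deep structure is a rooted
binary tree on the clade labels.  For n labels there are (2n−3)!! such
trees — 945 for six clades — enumerated exhaustively by recursive leaf
insertion into every branch.  Monophyly statements partition the space:
Scleroglossa (the five non-Iguania clades monophyletic) is satisfied by
(2(n−1)−3)!! = 105 trees; a three-clade Toxicofera by 3 × 15 = 45; 795
satisfy neither.  The enumeration doubles as the search space for the
constrained likelihood analyses: rather than heuristic tree search, each
backbone is expanded with fixed within-clade subtrees and scored exactly
within this space.  To keep the per-gene cost at desk scale, each class's
trees are first screened at fixed starting branch lengths and only the
top-k are branch-length optimized (screen-then-polish); with the class
maxima separated by many log-likelihood units this recovers the class
maximum in practice.

## Likelihood engine

Felsenstein pruning over time-reversible models (JC/HKY/GTR and k-state
Mk), diagonalized through the π-symmetrized rate matrix, with
discrete-gamma rate categories (category means of an equal-probability
partition) and an optional invariant class; per-site scaling guards
against underflow.  Branch lengths are optimized coordinate-wise with
bounded Brent iterations (log-likelihood tolerance 1e−6, branch bounds
[1e−8, 20], default Brent tolerance 1e−8) — monotone by construction.
Per-site ML rates on a fixed ultrametric chronogram are found with a
coarse vectorized log-grid followed by Brent refinement per unique site
pattern; invariant sites are assigned rate 0, and the upper bound defaults
to 20 substitutions/site per tree depth.  Model choice, when requested, is
a BIC sweep over {JC, HKY, GTR} × {+Γ, +Γ+I} with empirical frequencies
and short bounded fits of the exchangeabilities.

## AU test

Per gene, only the three class maxima are compared (the practical
simplification for this hypothesis space).  Site log-likelihoods are
resampled by multiscale RELL bootstrap at the ten standard scales
0.5…1.4 with 10,000 replicates by default; ties split their count evenly.
Winning proportions are fitted on the probit scale as
bp(r) = Φ(−(d√r + c/√r)) by weighted least squares (binomial delta-method
weights), and p_AU = Φ(−(d − c)).  Degenerate proportion vectors
short-circuit to p ∈ {0, 1}; a failed fit falls back to the scale-1
proportion with a flag.  Second-stage refinements of the reference
implementation are not reproduced; on the calibration test (data simulated
on a topology inside the candidate set) the rejection rate of the true
topology stays below the nominal level.  Genes whose confidence set
(p > 0.05) keeps ≥2 classes are "ambiguous".

## Informativeness and quartet signal/noise

Per-site informativeness is ρ(t; λ) = 16 λ t e^(−4λt): it vanishes at
t = 0, peaks at t = 1/(4λ), and for a fixed target depth t is maximized
by the optimal rate λ = 1/(4t).  This form satisfies both stationarity
properties that define the framework's "theoretical optimum rate"; the
constant 16 only scales profiles and cancels in the height-standardized
view.  Dataset profiles are sums over sites.

Quartet resolution probabilities take one internode (duration t0) and the
four subtending lineages (durations to the present).  For each site rate,
the probabilities of the three parsimony-informative pattern classes
(xxyy supporting the true internode; xyxy/xyyx supporting the two wrong
ones) are computed exactly from the k-state symmetric process by summing
over the internal states of the five-branch tree.  The gene-level outcome
— most supporting sites wins, any tie at the top is a polytomy — is then
evaluated by seeded Monte Carlo over per-site categorical draws (default
5,000 replicates).  QIRP + QIHP + QIPP = 1 by construction; the
acceptance surface is agreement with a fully independent Monte-Carlo
oracle that simulates character evolution down the quartet.  Joint
backbone signal multiplies per-internode QIRP under independence.
Internode geometries are read off a chronogram's clade-level backbone;
because the tree is ultrametric the subtending durations are simply the
ages of the internode's two ends.

## Tree-independent site rates and removal

OV is the fraction of mismatching observed taxon pairs per site
(ambiguity and gaps excluded from pairs).  TIGER scores site i by the mean
over other sites j of the fraction of j's state sets nested inside some
state set of i (higher = more agreement = slower); the original rate
binning is omitted because only rankings are used, and the computation is
O(sites²) — large matrices are subsampled.  Ranked removal strips a fixed
number of fastest sites per step (default 500), re-infers a tree, and
records which reference backbone splits persist.  The built-in estimator
is neighbor joining (scikit-bio) on ML distances: closed-form JC, or
mixture-aware pairwise ML under any engine model — the latter matters
because closed-form JC saturates badly under +Γ+I rate variation at these
depths.  A PHYLIP export hook serves external ML programs.

## Composition and lineage rates

Composition profiles count unambiguous bases per taxon (and per gene);
the homogeneity test is the standard taxa × 4 chi-square on margins.
AT-skew clustering is average-linkage agglomeration on Euclidean distances
between per-gene skew vectors; genes missing for a taxon are imputed with
that taxon's across-gene mean and flagged.  The phylogenetic ANOVA takes
the ordinary one-way F on the observed trait and derives its null from
Brownian-motion simulation on the tree, with σ² estimated by independent
contrasts; p is the fraction of simulated F ≥ observed.  Clade rates pool
root-to-tip distances over a (sub)sample of trees × member terminals and
report means with empirical 2.5–97.5% intervals; "significantly faster"
means non-overlapping intervals.  Whether to pool across terminals or
average per tree first is a free choice; we pool.

## Synthetic data generator

The generator emulates the squamate scenario rather than any particular
dataset: an ingroup crown at 190 Ma (outgroup split 240 Ma), backbone
internodes drawn uniformly from [4.6, 8.7] Ma along a configurable true
backbone (Scleroglossa-type by default), Yule-like within-clade trees with
crown ages at 55–80% of each stem age, and 46 terminals split 12/5/6/6/7/9
across Iguania/Gekkota/Scincoidea/Lacertoidea/Anguimorpha/Serpentes plus
the outgroup.  Sequences evolve by HKY (κ = 3) with +Γ(0.8)+I(0.2) site
rates at a base rate of 0.002 substitutions/site/Ma — chosen so that
per-site ML rates put the dataset informativeness peak around 80–120 Ma,
i.e. clearly shallower than the radiation, which is the regime under
study.  Gene lengths are log-normal (median ~1 kb, clipped to
0.3–3 kb, 46 genes); whole genes go missing per taxon with probability
0.1, mimicking phylogenomic matrix sparsity.

Two non-sister clades (Iguania, Serpentes) carry the biases, inherited
from their stem branches tipward: a 1.6× rate multiplier, and a
nonstationary equilibrium-frequency switch that makes their composition
+1.3 percentage points AT-rich at the expense of G+C and tilts the AT
pool toward A.  The equilibrium skew target (0.25) is deliberately larger
than the realized tip-level skew: composition equilibrates only partially
over the clade depths (~35% of the shift reaches the tips), so this
setting produces a realized inter-group skew separation of ~0.08 — enough
for the skew signature to be a detectable clade-level pattern, which is
the phenomenon the generator exists to emulate.  Morphology is simulated
as symmetric 2-state Mk at 0.0015 changes/Ma, placing its informativeness
peak near 165 Ma — older than the molecular peak, the slow-character
regime.

What the generator does *not* emulate: incomplete lineage sorting (no
coalescent gene trees — gene trees differ from the species tree only
through estimation noise), alignment uncertainty and indels, codon
structure, selection, and within-gene rate autocorrelation.  Passing
tests therefore demonstrate that the diagnostics behave correctly under
substitution noise, rate heterogeneity and compositional nonstationarity
— not that they would be robust to ILS or alignment error on real data.

## Problem sizes and numerical choices

Tests and the bundled analyses run the pipeline at deliberately modest
sizes chosen as desk-scale defaults: 6–16 taxa and a few hundred sites
for engine validation; 200 simulated genes for AU calibration (2,000 RELL
replicates per scale there; 10,000 in production use); 20,000 replicates
for the quartet Monte-Carlo cross-check; 8–12 genes per seed for the
bias-recovery studies, with clade rates re-estimated on one representative
terminal per clade.  Ties in rankings break by site index; RELL winner
ties split evenly; zero-length branches are kept as polytomies; all
stochastic steps take explicit seeds and identical seeds give
bit-identical outputs.

## Known limitations

The AU implementation fits the primary (d, c) probit model only.  TIGER
is quadratic in sites.  `best_tree_in_class` guarantees the class maximum
only within the screen-then-polish heuristic.  The quartet framework
conditions on the given geometry and treats sites independently.  The
phylogenetic ANOVA assumes Brownian trait evolution with a single σ².
Clade-rate recovery is estimator-dependent: naive saturating distance
estimators understate the planted multiplier, which is itself a finding
the package surfaces.
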