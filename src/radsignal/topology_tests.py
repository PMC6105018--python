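"""Approximately unbiased (AU) topology test via multiscale RELL bootstrap.

The AU test resamples per-site log-likelihoods (RELL: no re-optimization)
at several scale factors r, records how often each candidate topology wins
each replicate, and fits the winning proportions bp(r) on the probit scale

    bp(r) = Phi(-(d sqrt(r) + c / sqrt(r)))

by weighted least squares; the signed distance d and curvature c give the
p-value p_AU = Phi(-(d - c)).  Topologies with p above a threshold form the
confidence set: the set of trees that cannot be statistically rejected as
the best explanation of the data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

#: the ten standard bootstrap scales of the reference implementation
DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))
DEFAULT_REPLICATES = 10_000


def rell_bootstrap(site_loglik_matrix: np.ndarray,
                   scales: Sequence[float] = DEFAULT_SCALES,
                   replicates: int = DEFAULT_REPLICATES,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multiscale RELL winning proportions.

    ``site_loglik_matrix`` is (topologies x sites).  For each scale r,
    ceil(r * n_sites) site columns are drawn with replacement and summed;
    the proportion of replicates each topology wins is recorded, with ties
    split equally among the tied topologies.  Returns (scales x topologies).
    """
    L = np.asarray(site_loglik_matrix, dtype=float)
    if L.ndim != 2:
        raise ValueError("site log-likelihood matrix must be 2-D")
    n_topo, n_sites = L.shape
    if min(s for s in scales) <= 0:
        raise ValueError("scales must be positive")
    if replicates < 100:
        raise ValueError("need >=100 replicates")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = np.zeros((len(scales), n_topo))
    if n_topo == 1:
        out[:] = 1.0
        return out
    p_uniform = np.full(n_sites, 1.0 / n_sites)
    for si, r in enumerate(scales):
        m = int(np.ceil(r * n_sites))
        counts = rng.multinomial(m, p_uniform, size=replicates)  # (rep, sites)
        sums = counts @ L.T  # (rep, topo)
        best = sums.max(axis=1, keepdims=True)
        winners = np.isclose(sums, best, rtol=0.0, atol=1e-9)
        out[si] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0)
    return out / replicates


@dataclasses.dataclass
class AUResult:
    """AU test outcome for one topology."""

    p_value: float
    bootstrap_proportions: np.ndarray
    d: float | None = None
    c: float | None = None
    fallback: bool = False


def au_pvalue(proportions: np.ndarray, scales: Sequence[float] = DEFAULT_SCALES,
              replicates: int = DEFAULT_REPLICATES) -> AUResult:
    """AU p-value for one topology from its per-scale winning proportions.

    Degenerate proportions (identically 0 or 1) short-circuit to p = 0 or 1;
    a failed probit fit falls back to the scale-1 bootstrap proportion with
    ``fallback=True``.
    """
    bp = np.asarray(proportions, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if bp.shape != scales.shape:
        raise ValueError("one proportion per scale required")
    if np.all(bp >= 1.0 - 1e-12):
        return AUResult(1.0, bp)
    if np.all(bp <= 1e-12):
        return AUResult(0.0, bp)
    eps = 1.0 / (2.0 * replicates)
    interior = (bp > 0.0) & (bp < 1.0)
    use = interior if interior.sum() >= 3 else np.ones_like(interior)
    bpc = np.clip(bp[use], eps, 1.0 - eps)
    r = scales[use]
    y = -ndtri(bpc)  # d*sqrt(r) + c/sqrt(r)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    phi = np.exp(-0.5 * y ** 2) / np.sqrt(2 * np.pi)
    w = replicates * phi ** 2 / (bpc * (1.0 - bpc))
    try:
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
        d, c = float(beta[0]), float(beta[1])
        p = float(ndtr(-(d - c)))
    except np.linalg.LinAlgError:
        scale1 = int(np.argmin(np.abs(scales - 1.0)))
        return AUResult(float(bp[scale1]), bp, fallback=True)
    if not np.isfinite(p):
        scale1 = int(np.argmin(np.abs(scales - 1.0)))
        return AUResult(float(bp[scale1]), bp, fallback=True)
    return AUResult(p, bp, d=d, c=c)


def au_test(site_loglik_matrix: np.ndarray,
            scales: Sequence[float] = DEFAULT_SCALES,
            replicates: int = DEFAULT_REPLICATES,
            seed: int | np.random.Generator = 0) -> list[AUResult]:
    """RELL bootstrap + AU p-value for every topology in the matrix."""
    props = rell_bootstrap(site_loglik_matrix, scales, replicates, seed)
    return [au_pvalue(props[:, j], scales, replicates)
            for j in range(props.shape[1])]


@dataclasses.dataclass
class GeneVerdict:
    """Confidence-set composition for one gene over the hypothesis classes."""

    gene: str
    p_values: dict[str, float]
    confidence_set: tuple[str, ...]
    verdict: str
    low_power: bool = False

    @property
    def ambiguous(self) -> bool:
        return len(self.confidence_set) >= 2


def _verdict(confidence_set: Sequence[str]) -> str:
    if len(confidence_set) >= 2:
        return "ambiguous"
    return f"supports_{confidence_set[0]}_only"


def gene_confidence_sets(gene_site_logliks: Mapping[str, Mapping[str, np.ndarray]],
                         threshold: float = 0.05,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         replicates: int = DEFAULT_REPLICATES,
                         seed: int = 0,
                         low_power_variable_sites: Mapping[str, int] | None = None,
                         ) -> list[GeneVerdict]:
    """Per-gene AU confidence sets over hypothesis-class representatives.

    ``gene_site_logliks[gene][class_label]`` holds the per-site
    log-likelihood vector of that class's best tree for that gene.  A gene
    is *ambiguous* when at least two classes survive in its confidence set.
    """
    rng = np.random.default_rng(seed)
    out: list[GeneVerdict] = []
    for gene, per_class in gene_site_logliks.items():
        labels = list(per_class)
        L = np.vstack([np.asarray(per_class[c], dtype=float) for c in labels])
        results = au_test(L, scales, replicates, rng)
        pvals = {c: res.p_value for c, res in zip(labels, results)}
        conf = tuple(c for c in labels if pvals[c] > threshold)
        if not conf:  # the ML topology always stays in the set
            conf = (labels[int(np.argmax([t.sum() for t in L]))],)
        low = False
        if low_power_variable_sites is not None:
            low = low_power_variable_sites.get(gene, 10 ** 9) < 50
        out.append(GeneVerdict(gene, pvals, conf, _verdict(conf), low))
    return out


def ambiguity_rate(verdicts: Sequence[GeneVerdict]) -> float:
    """Fraction of genes whose confidence set holds >=2 classes."""
    if not verdicts:
        raise ValueError("no verdicts")
    return sum(v.ambiguous for v in verdicts) / len(verdicts)


def verdicts_to_frame(verdicts: Sequence[GeneVerdict]):
    import pandas as pd

    rows = []
    for v in verdicts:
        row = {"gene": v.gene}
        row.update({f"p_{c}": p for c, p in v.p_values.items()})
        row["confidence_set"] = "|".join(v.confidence_set)
        row["verdict"] = v.verdict
        row["low_power"] = v.low_power
        rows.append(row)
    return pd.DataFrame(rows)
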