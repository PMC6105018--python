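"""Backbone internode arithmetic.

Time-calibration studies bracket the span of an ancient radiation — the
interval between the crown age of the whole clade and the last backbone
divergence — without resolving the individual internodes.  Dividing the
span by the number of backbone internodes gives their average duration:
for crown Squamata, published spans of 23.1-43.5 Ma over the five
internodes separating the six major clades give averages of 4.6-8.7 Ma,
the short-and-deep branches at the heart of the resolution problem.
"""

from __future__ import annotations


def average_internode_length(total_span: float, n_internodes: int) -> float:
    """Average backbone internode duration, span / internode count."""
    if n_internodes < 1:
        raise ValueError("need at least one internode")
    if total_span < 0:
        raise ValueError("time span must be non-negative")
    return total_span / n_internodes


def backbone_internode_count(n_clades: int) -> int:
    """Internodes along a fully resolved backbone joining n successive
    clades (a ladder of n-1 divergences spans n-1 internodes)."""
    if n_clades < 2:
        raise ValueError("need at least two clades")
    return n_clades - 1
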