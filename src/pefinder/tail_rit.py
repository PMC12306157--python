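"""Thymine-tail scoring and REP / RIT classification.

Rho-independent terminators (RITs) are hairpins immediately followed by
a thymine-rich 3' tail; repetitive extragenic palindromes (REPs) lack
that tail. The tail score over the up-to-15 nt immediately 3' of the
hairpin is

    score = - sum_{i=1..L} prod_{j=1..i} w(x_j)

with w(T) = 0.9 and w(other) = 0.6, reading x_1 as the base nearest the
hairpin. Each additional T extends the run of large products, so more
negative means more T-rich: a 15xT tail scores about -7.15 and a 15xA
tail about -1.50. Candidates scoring at or below the cutoff (default
-2.5) are classified RIT; everything else is a putative REP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .hairpin_energy import Hairpin

__all__ = ["TailModel", "tail_score", "classify"]

_EPS = 1e-9
_DNA = frozenset("ACGTN")


@dataclass(frozen=True)
class TailModel:
    window: int = 15
    w_t: float = 0.9
    w_other: float = 0.6
    tail_cutoff: float = -2.5

    def __post_init__(self) -> None:
        if not (0 < self.w_other < self.w_t < 1):
            raise ValueError("weights must satisfy 0 < w_other < w_t < 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def tail_score(tail: str, m: TailModel = TailModel()) -> float:
    """Weighted T-richness of a 3' tail (0 for an empty tail).

    ``tail`` is the sequence immediately 3' of the hairpin on the
    element's strand, truncated to the model window (and shorter still
    at region edges). N weighs as a non-T base.
    """
    bad = set(tail) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in tail: {sorted(bad)}")
    prod = 1.0
    total = 0.0
    for base in tail[: m.window]:
        prod *= m.w_t if base == "T" else m.w_other
        total += prod
    return -total


def classify(h: "Hairpin", tail: str, m: TailModel = TailModel()) -> str:
    """Label a surviving hairpin RIT (T-rich tail) or REP (otherwise).

    Total and single-valued: every candidate gets exactly one label, so
    REP count + RIT count equals the surviving-candidate count. The
    cutoff is inclusive (a score of exactly -2.5 is a RIT).
    """
    return "RIT" if tail_score(tail, m) <= m.tail_cutoff + _EPS else "REP"
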