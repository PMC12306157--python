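"""Stem-loop structure inference and energy scoring.

The energy model is an additive per-pair scheme (kcal/mol): G-C at
-2.3, A-T at -0.9, G·T wobble at +1.3, a 3.5 penalty per mismatched
pair, a 6.0 penalty per single-sided gap (bulge) and a linear loop term
loop_coeff * (loop_len - loop_offset) with defaults 1 * (n - 2). A
hairpin is accepted when its total energy is at or below the cutoff
(default -0.2 kcal/mol; more negative = more stable).

All default constants are one-decimal rationals, so sums are computed
in integer tenths and converted once — classification is bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .palindrome_scan import ArmPair

__all__ = [
    "EnergyModel",
    "Hairpin",
    "infer_structure",
    "score_hairpin",
    "passes_energy",
    "GC",
    "AT",
    "GT",
    "MISMATCH",
    "GAP",
]

GC = "GC"
AT = "AT"
GT = "GT"
MISMATCH = "MISMATCH"
GAP = "GAP"

_EPS = 1e-9


@dataclass(frozen=True)
class EnergyModel:
    e_gc: float = -2.3
    e_at: float = -0.9
    e_gt: float = 1.3
    mismatch_pen: float = 3.5
    gap_pen: float = 6.0
    loop_coeff: float = 1.0
    loop_offset: int = 2
    hairpin_cutoff: float = -0.2

    def pair_energy(self, cls: str) -> float:
        return {
            GC: self.e_gc,
            AT: self.e_at,
            GT: self.e_gt,
            MISMATCH: self.mismatch_pen,
            GAP: self.gap_pen,
        }[cls]


@dataclass
class Hairpin:
    """A stem-loop: ordered pair classes (outermost first), loop, energy."""

    arm_pair: ArmPair
    stem: tuple[str, ...]
    loop_len: int
    energy: Optional[float] = None

    @property
    def stem_pairs(self) -> int:
        """Number of actually paired stem positions (gaps excluded)."""
        return sum(1 for c in self.stem if c != GAP)


def _classify(a: str, b: str) -> str:
    pair = frozenset((a, b))
    if pair == frozenset("GC"):
        return GC
    if pair == frozenset("AT"):
        return AT
    if pair == frozenset("GT"):
        return GT
    return MISMATCH


def infer_structure(p: ArmPair, region_seq: str) -> Hairpin:
    """Pair the arms of ``p`` anti-parallel and classify each position.

    Within each exactly-paired segment, left-arm offset t pairs with
    right-arm offset (len - 1 - t). Between consecutive segments the
    facing insertions pair off as MISMATCH positions and any one-sided
    excess contributes GAP entries. The loop is the unpaired gap between
    the innermost left and right arm ends.
    """
    if p.left_len < 1 or p.right_len < 1:
        raise ValueError("zero-length arm")
    stem: list[str] = []
    for idx, (ls, le, rs, re) in enumerate(p.segments):
        n = le - ls
        if n != re - rs:
            raise ValueError("segment arms of unequal length")
        for t in range(n):
            stem.append(_classify(region_seq[ls + t], region_seq[re - 1 - t]))
        if idx + 1 < len(p.segments):
            l2s = p.segments[idx + 1][0]
            r2e = p.segments[idx + 1][3]
            dl = l2s - le
            dr = rs - r2e
            m = min(dl, dr)
            stem.extend([MISMATCH] * m)
            stem.extend([GAP] * ((dl - m) + (dr - m)))
    return Hairpin(arm_pair=p, stem=tuple(stem), loop_len=p.loop_len)


def _tenths(x: float) -> Optional[int]:
    t = round(x * 10)
    return t if abs(x * 10 - t) < 1e-6 else None


def score_hairpin(h: Hairpin, m: EnergyModel = EnergyModel()) -> float:
    """Total hairpin energy; stored on the Hairpin and returned.

    energy = sum of per-position pair energies
             + loop_coeff * (loop_len - loop_offset)

    The loop term applies literally even for loops of 0-2 nt (where it
    is <= 0); admissibility of short loops is governed by the structural
    filters, not by the energy.
    """
    terms = [m.pair_energy(c) for c in h.stem]
    terms.append(m.loop_coeff * (h.loop_len - m.loop_offset))
    tenths = [_tenths(t) for t in terms]
    if all(t is not None for t in tenths):
        energy = sum(tenths) / 10.0  # exact decimal arithmetic
    else:
        energy = float(sum(terms))
    h.energy = energy
    return energy


def passes_energy(h: Hairpin, m: EnergyModel = EnergyModel()) -> bool:
    """Inclusive stability test: energy at or below the cutoff."""
    if h.energy is None:
        raise ValueError("hairpin not scored")
    return h.energy <= m.hairpin_cutoff + _EPS
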