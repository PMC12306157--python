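"""Seed-and-extend detection of palindromic arm pairs.

The scan decomposes an intergenic sequence into k-mers (default k = 6),
finds exact reverse-complementary k-mer pairs within a 50 bp span,
extends each pair in both directions while the newly added base pair is
Watson-Crick or a G·T wobble, and finally assembles nearby extended
pairs across short (default <= 2 nt) interruptions into a single
imperfect stem.

All coordinates here are offsets within the scanned sequence, 0-based
half-open. Seeding is exact (the wobble is admitted only during
extension, where the energy model can price it); k-mers containing N
never seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .genome_io import revcomp

__all__ = [
    "ScanConfig",
    "ArmPair",
    "Kmer",
    "kmerize",
    "find_seed_pairs",
    "extend_pair",
    "assemble_pairs",
    "scan_sequence",
]

# Base pairs accepted while growing a stem: Watson-Crick plus G.T wobble.
_VALID_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)


def pairs_ok(a: str, b: str) -> bool:
    return (a, b) in _VALID_PAIRS


@dataclass(frozen=True)
class ScanConfig:
    """All tunable parameters of the detection method.

    Defaults are the method's standard settings: hexamer seeds, 50 bp
    seed span, assembly gaps up to 2 nt, arm length 5-32 nt, loop at
    most 11 nt, stem at least 1 pair, stem-to-loop ratio at least 0.2,
    elements at least 10 nt overall, and a 200 nt bound on the distance
    between an element and the nearest gene 5' end it faces.
    ``max_upstream_gene_distance`` optionally bounds the plain gap to
    the nearest upstream gene instead (used for whole-genome surveys
    where every intergenic region should be reachable).
    """

    k: int = 6
    max_span: int = 50
    max_gap: int = 2
    min_palindrome: int = 5
    max_palindrome: int = 32
    max_loop: int = 11
    min_stem: int = 1
    min_stem_loop_ratio: float = 0.2
    max_gene_distance: Optional[int] = 200
    max_upstream_gene_distance: Optional[int] = None
    min_element_len: int = 10
    span_mode: str = "outer"
    keep_edge: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.max_span < 2 * self.k:
            raise ValueError("max_span must be >= 2k")
        for name in (
            "max_gap",
            "min_palindrome",
            "max_palindrome",
            "max_loop",
            "min_stem",
            "min_element_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.min_stem_loop_ratio <= 0:
            raise ValueError("min_stem_loop_ratio must be positive")
        if self.span_mode not in ("outer", "start"):
            raise ValueError("span_mode must be 'outer' or 'start'")

    @classmethod
    def mg1655(cls) -> "ScanConfig":
        """Settings for an exhaustive E. coli K-12 MG1655 survey.

        The longest MG1655 intergenic spacer is 6,176 bp, so the
        upstream-gene distance bound is set to 6,200 nt (and the 5'-end
        proximity rule is disabled) so that every intergenic region is
        searched in full.
        """
        return cls(max_gene_distance=None, max_upstream_gene_distance=6200)


class Kmer(NamedTuple):
    pos: int
    seq: str
    seedable: bool


@dataclass(frozen=True)
class ArmPair:
    """Two non-crossing arms of a (possibly imperfect) palindrome.

    ``segments`` lists the exactly-paired blocks ``(ls, le, rs, re)``
    that assembly stitched together, outermost first; an unassembled
    pair has a single segment spanning both arms. Inserted bases between
    consecutive segments are exposed via :meth:`gap_positions`.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    segments: tuple[tuple[int, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.left_start >= self.left_end or self.right_start >= self.right_end:
            raise ValueError("arms must be non-empty")
        if self.left_end > self.right_start:
            raise ValueError("arms must not cross (left_end <= right_start)")
        if not self.segments:
            object.__setattr__(
                self,
                "segments",
                ((self.left_start, self.left_end, self.right_start, self.right_end),),
            )

    @property
    def left_len(self) -> int:
        return self.left_end - self.left_start

    @property
    def right_len(self) -> int:
        return self.right_end - self.right_start

    @property
    def loop_len(self) -> int:
        return self.right_start - self.left_end

    @property
    def outer_span(self) -> int:
        return self.right_end - self.left_start

    def gap_positions(self) -> list[tuple[str, int]]:
        """Unpaired inserted positions between segments as (arm, offset).

        Facing insertions of equal length on the two arms pair off as
        mismatches and are not reported here; only the one-sided excess
        (a bulge) counts as a gap.
        """
        gaps: list[tuple[str, int]] = []
        for (l1s, l1e, r1s, r1e), (l2s, l2e, r2s, r2e) in zip(
            self.segments, self.segments[1:]
        ):
            dl = l2s - l1e
            dr = r1s - r2e
            m = min(dl, dr)
            for off in range(l1e, l1e + dl - m):
                gaps.append(("L", off))
            for off in range(r2e, r2e + dr - m):
                gaps.append(("R", off))
        return gaps


def kmerize(region_seq: str, k: int) -> list[Kmer]:
    """All positioned k-mers of a sequence; those containing N cannot seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return [
        Kmer(i, region_seq[i : i + k], "N" not in region_seq[i : i + k])
        for i in range(len(region_seq) - k + 1)
    ]


def find_seed_pairs(region_seq: str, cfg: ScanConfig) -> list[ArmPair]:
    """Exact reverse-complementary k-mer pairs within the span threshold.

    Returns every (i, j) with ``i + k <= j``, ``kmer(j) == revcomp(kmer(i))``
    and span within ``cfg.max_span``, where the span is the full outer
    extent ``(j + k) - i`` in the default ``outer`` mode or the start
    offset ``j - i`` in ``start`` mode. Deterministic order by (i, j).
    """
    k = cfg.k
    n = len(region_seq)
    if n < 2 * k:
        return []
    positions: dict[str, list[int]] = {}
    kmers = kmerize(region_seq, k)
    for km in kmers:
        if km.seedable:
            positions.setdefault(km.seq, []).append(km.pos)

    out: list[ArmPair] = []
    for km in kmers:
        if not km.seedable:
            continue
        i = km.pos
        target = revcomp(km.seq)
        j_max = i + cfg.max_span - k if cfg.span_mode == "outer" else i + cfg.max_span
        for j in positions.get(target, ()):
            if i + k <= j <= j_max:
                out.append(ArmPair(i, i + k, j, j + k))
    return out


def extend_pair(p: ArmPair, region_seq: str) -> ArmPair:
    """Maximal symmetric extension of a seed pair.

    Grows inward (pairing ``seq[left_end]`` with ``seq[right_start-1]``)
    and outward (pairing ``seq[left_start-1]`` with ``seq[right_end]``)
    while the added pair is Watson-Crick or G·T wobble, the arms do not
    cross, and sequence bounds are respected. Extension stops at the
    first non-pair: internal mismatches are never absorbed here — they
    can only enter a stem via assembly of separate pairs.
    """
    if len(p.segments) != 1:
        raise ValueError("extend_pair applies to single-segment pairs")
    ls, le, rs, re = p.left_start, p.left_end, p.right_start, p.right_end
    s = region_seq
    while rs - le >= 2 and pairs_ok(s[le], s[rs - 1]):
        le += 1
        rs -= 1
    while ls >= 1 and re < len(s) and pairs_ok(s[ls - 1], s[re]):
        ls -= 1
        re += 1
    return ArmPair(ls, le, rs, re)


def _mergeable(a: ArmPair, b: ArmPair, max_gap: int) -> bool:
    """Can b (inner) be stitched onto a (outer) across short interruptions?"""
    dl = b.left_start - a.left_end
    dr = a.right_start - b.right_end
    return 0 <= dl <= max_gap and 0 <= dr <= max_gap


def _merge(a: ArmPair, b: ArmPair) -> ArmPair:
    return ArmPair(
        a.left_start,
        b.left_end,
        b.right_start,
        a.right_end,
        segments=a.segments + b.segments,
    )


def _contained(p: ArmPair, q: ArmPair) -> bool:
    """p strictly contained in q, arm-wise."""
    return (
        p != q
        and q.left_start <= p.left_start
        and p.left_end <= q.left_end
        and q.right_start <= p.right_start
        and p.right_end <= q.right_end
    )


def assemble_pairs(pairs: list[ArmPair], cfg: ScanConfig) -> list[ArmPair]:
    """Stitch extended pairs separated by <= max_gap nt on both arms.

    Merging repeats to a fixed point; identical spans are collapsed and
    any pair arm-wise contained in another is dropped, so the result is
    a deduplicated, maximal set.
    """
    def key(p: ArmPair) -> tuple:
        return (p.left_start, p.left_end, p.right_start, p.right_end, p.segments)

    work = sorted(set(pairs), key=key)
    changed = True
    while changed:
        changed = False
        for ai in range(len(work)):
            for bi in range(len(work)):
                if ai == bi:
                    continue
                a, b = work[ai], work[bi]
                if _mergeable(a, b, cfg.max_gap):
                    merged = _merge(a, b)
                    work = [p for n, p in enumerate(work) if n not in (ai, bi)]
                    work.append(merged)
                    work = sorted(set(work), key=key)
                    changed = True
                    break
            if changed:
                break

    # collapse identical spans (segments may differ after merging)
    by_span: dict[tuple[int, int, int, int], ArmPair] = {}
    for p in sorted(work, key=key):
        span = (p.left_start, p.left_end, p.right_start, p.right_end)
        by_span.setdefault(span, p)
    unique = list(by_span.values())
    return sorted(
        (p for p in unique if not any(_contained(p, q) for q in unique)), key=key
    )


def scan_sequence(region_seq: str, cfg: ScanConfig) -> list[ArmPair]:
    """Full seed → extend → dedup → assemble scan of one sequence."""
    seeds = find_seed_pairs(region_seq, cfg)
    extended = {extend_pair(p, region_seq) for p in seeds}
    return assemble_pairs(list(extended), cfg)
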