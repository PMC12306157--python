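"""Cross-group consensus-motif similarity.

Motif discovery and matching themselves are external (MEME/TomTom
style tools); this module consumes their tabulated output — for each
unordered pair of motif groups A, B the number of unique motifs Na and
Nb and the number of similar motifs Nab identified between them — and
computes the similarity score

    score(A, B) = Nab / (Na + Nb)   in [0, 0.5]

together with the symmetric score matrix and each group's total number
of significant matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "MotifGroupSummary",
    "similarity_score",
    "similarity_matrix",
    "read_pairs_tsv",
]


@dataclass
class MotifGroupSummary:
    group_id: str
    n_motifs: int
    matches: dict = field(default_factory=dict)


def similarity_score(Na: int, Nb: int, Nab: int) -> float:
    """Nab / (Na + Nb); maximal (0.5) at full overlap of equal groups."""
    if Na < 1 or Nb < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= Nab <= min(Na, Nb)):
        raise ValueError(f"Nab={Nab} must lie in [0, min(Na, Nb)={min(Na, Nb)}]")
    return Nab / (Na + Nb)


def similarity_matrix(
    groups: list[MotifGroupSummary],
) -> tuple[pd.DataFrame, pd.Series]:
    """Symmetric score matrix and per-group total significant matches.

    The diagonal is set to 0.5 by convention (self-similarity is
    maximal) and excluded from the per-group totals. Group order is
    input order. Asymmetric match counts (Nab != Nba where both are
    given) raise.
    """
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group ids")
    sizes = {g.group_id: g.n_motifs for g in groups}
    for g in groups:
        for other, nab in g.matches.items():
            if other not in sizes:
                raise ValueError(f"unknown group {other!r} in matches of {g.group_id!r}")
    for a in groups:
        for b_id, nab in a.matches.items():
            b = next(g for g in groups if g.group_id == b_id)
            if a.group_id in b.matches and b.matches[a.group_id] != nab:
                raise ValueError(
                    f"asymmetric matches between {a.group_id!r} and {b_id!r}: "
                    f"{nab} vs {b.matches[a.group_id]}"
                )

    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    totals = pd.Series(0, index=ids, dtype=int, name="total_matches")
    for a in groups:
        mat.loc[a.group_id, a.group_id] = 0.5
        for b_id, nab in a.matches.items():
            if b_id == a.group_id:
                continue
            s = similarity_score(sizes[a.group_id], sizes[b_id], nab)
            mat.loc[a.group_id, b_id] = s
            mat.loc[b_id, a.group_id] = s
            totals[a.group_id] += nab
    # ensure totals count each unordered pair once per group even if
    # only one direction was provided
    seen = set()
    totals[:] = 0
    for a in groups:
        for b_id, nab in a.matches.items():
            if b_id == a.group_id:
                continue
            key = frozenset((a.group_id, b_id))
            if key in seen:
                continue
            seen.add(key)
            totals[a.group_id] += nab
            totals[b_id] += nab
    return mat, totals


def read_pairs_tsv(path) -> list[MotifGroupSummary]:
    """Read a (group_a, group_b, Na, Nb, Nab) TSV into group summaries."""
    df = pd.read_csv(path, sep="\t", dtype={"group_a": str, "group_b": str})
    required = {"group_a", "group_b", "Na", "Nb", "Nab"}
    if not required.issubset(df.columns):
        raise ValueError(f"pairs TSV must have columns {sorted(required)}")
    groups: dict[str, MotifGroupSummary] = {}

    def ensure(gid: str, n: int) -> MotifGroupSummary:
        if gid in groups:
            if groups[gid].n_motifs != n:
                raise ValueError(f"inconsistent size for group {gid!r}")
            return groups[gid]
        groups[gid] = MotifGroupSummary(group_id=gid, n_motifs=int(n))
        return groups[gid]

    for row in df.itertuples():
        a = ensure(row.group_a, row.Na)
        b = ensure(row.group_b, row.Nb)
        a.matches[b.group_id] = int(row.Nab)
        b.matches[a.group_id] = int(row.Nab)
    return list(groups.values())
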