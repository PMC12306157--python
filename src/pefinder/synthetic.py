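"""Synthetic annotated genomes with implanted palindromic elements.

The generator emits exactly what the pipeline consumes — a FASTA
chromosome, a GFF3 gene annotation and a truth BED — with stem-loop
palindromes (REP-like, no tail) and terminator hairpins (RIT-like,
U-rich tail) spliced into intergenic gaps at controlled distances from
the upstream gene's stop codon. Every stage of the workflow is thereby
testable without downloading a real assembly.

Background is i.i.d. with a configurable GC fraction; implanted arms
are GC-rich so the implants dominate any chance background palindrome
at the same locus. For REP implants (and the reverse-orientation
context of every implant) the 15 nt of flanking background are redrawn
in the rare case they would score as a terminator tail by chance, so a
"clean" fixture has unambiguous kinds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .genome_io import GeneFeature, GenomeRecord, revcomp
from .pipeline import PECandidate
from .tail_rit import TailModel, tail_score

__all__ = [
    "ImplantSpec",
    "TruthElement",
    "SyntheticDataset",
    "make_genome",
    "make_gene_layout",
    "implant",
    "evaluate_recovery",
    "read_truth_bed",
    "RecoveryReport",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ImplantSpec:
    """One class of implants: hairpin geometry, arm composition, tail, count.

    RIT specs must carry a T-rich ``tail`` (e.g. 12xT); REP specs must
    not carry one. ``stop_gap`` pins the distance between the upstream
    gene's stop codon and the element start (drawn from [20, 40] nt
    when None).
    """

    kind: str
    arm_len: int = 8
    loop_len: int = 4
    arm_gc_fraction: float = 0.8
    tail: Optional[str] = None
    count: int = 1
    stop_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("REP", "RIT"):
            raise ValueError("kind must be REP or RIT")
        if self.kind == "RIT" and not self.tail:
            raise ValueError("RIT specs require a tail")
        if self.kind == "REP" and self.tail:
            raise ValueError("REP specs must not have a tail")
        if self.arm_len < 1 or self.loop_len < 0 or self.count < 1:
            raise ValueError("invalid implant geometry")


@dataclass(frozen=True)
class TruthElement:
    """Ground-truth location of one implanted element (hairpin span only)."""

    seq_id: str
    start: int
    end: int
    kind: str
    strand: str = "+"
    stop_gap: Optional[int] = None


@dataclass
class SyntheticDataset:
    record: GenomeRecord
    genes: list[GeneFeature]
    truth: list[TruthElement]
    paths: Optional[dict] = None


def make_genome(length: int, gc: float, seed: int, seq_id: str = "synth1") -> GenomeRecord:
    """I.i.d. random chromosome with P(G) = P(C) = gc/2; reproducible by seed."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return GenomeRecord(seq_id=seq_id, sequence=seq)


def make_gene_layout(
    length: int,
    n_genes: int,
    gene_len: int = 900,
    gap: int = 220,
    strand: str = "+",
    seq_id: str = "synth1",
) -> list[GeneFeature]:
    """Evenly spaced genes: ``gap`` nt of intergenic space before each gene.

    The default 220 nt gap keeps every implant within 200 nt of the
    next gene's 5' end, so implants survive the default gene-distance
    filter of the pipeline.
    """
    needed = n_genes * (gene_len + gap) + gap
    if needed > length:
        raise ValueError(
            f"{n_genes} genes of {gene_len} nt with {gap} nt gaps need "
            f"{needed} nt; genome has {length}"
        )
    return [
        GeneFeature(
            seq_id=seq_id,
            start=gap + i * (gene_len + gap),
            end=gap + i * (gene_len + gap) + gene_len,
            strand=strand,
            feature_class="gene",
            gene_id=f"g{i + 1:04d}",
        )
        for i in range(n_genes)
    ]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _safe_flank(
    rng: np.random.Generator,
    n: int,
    tm: TailModel,
    first: Optional[str] = None,
    last: Optional[str] = None,
    margin: float = 0.2,
) -> str:
    """Background-like flank that does not score as a terminator tail
    in either reading direction (with a safety margin), optionally with
    pinned first/last bases."""
    for _ in range(200):
        s = _random_seq(rng, n, 0.5)
        if first is not None:
            s = first + s[1:]
        if last is not None:
            s = s[:-1] + last
        safe = tm.tail_cutoff + margin
        if tail_score(s, tm) > safe and tail_score(revcomp(s), tm) > safe:
            return s
    raise RuntimeError("could not draw a tail-neutral flank")  # pragma: no cover


def implant(
    genome: GenomeRecord,
    genes: list[GeneFeature],
    elements: Sequence[ImplantSpec],
    seed: int,
    out_prefix=None,
    min_gene_margin: int = 20,
) -> SyntheticDataset:
    """Splice elements into intergenic gaps; emit FASTA + GFF3 + truth BED.

    Implants are placed left-to-right, one per intergenic gap between
    consecutive genes, at ``stop_gap`` nt downstream of the upstream
    gene's end (or a seeded draw from [min_gene_margin, 40]). An arm
    ``s`` is generated at the spec's GC fraction and the element is
    ``s + loop + revcomp(s)`` (+ tail for RITs). Same seed, same files.
    """
    rng = np.random.default_rng(seed)
    tm = TailModel()
    genes = sorted((g for g in genes if g.seq_id == genome.seq_id), key=lambda g: g.start)
    gaps = [
        (a.end, b.start)
        for a, b in zip(genes, genes[1:])
        if b.start - a.end >= min_gene_margin * 2
    ]
    todo: list[ImplantSpec] = []
    for spec in elements:
        todo.extend([spec] * spec.count)
    if len(todo) > len(gaps):
        raise ValueError(
            f"{len(todo)} implants requested but only {len(gaps)} usable intergenic gaps"
        )

    seq = list(genome.sequence)
    truth: list[TruthElement] = []
    for spec, (gap_start, gap_end) in zip(todo, gaps):
        g = (
            spec.stop_gap
            if spec.stop_gap is not None
            else int(rng.integers(min_gene_margin, 41))
        )
        arm = _random_seq(rng, spec.arm_len, spec.arm_gc_fraction)
        loop = _random_seq(rng, spec.loop_len, 0.5)
        elem = arm + loop + revcomp(arm)
        start = gap_start + g
        tail = spec.tail or ""
        if start + len(elem) + max(len(tail), tm.window) > gap_end:
            raise ValueError(
                f"implant {spec} does not fit in gap [{gap_start},{gap_end})"
            )
        seq[start : start + len(elem)] = elem
        after = elem_end = start + len(elem)
        if spec.kind == "RIT":
            seq[after : after + len(tail)] = tail
        else:
            # tail-neutral flank starting with C: the boundary pair C/C
            # (G/G read on the other strand) cannot extend the stem in
            # either orientation
            flank = _safe_flank(rng, tm.window, tm, first="C")
            seq[after : after + tm.window] = flank
        # reverse-orientation tail context (bases 5' of the hairpin);
        # pinned terminal C blocks outward stem extension against both
        # a C flank (REP) and a T tail (RIT) on either strand
        pre = _safe_flank(rng, tm.window, tm, last="C")
        seq[start - tm.window : start] = pre
        truth.append(
            TruthElement(
                seq_id=genome.seq_id,
                start=start,
                end=elem_end,
                kind=spec.kind,
                strand="+",
                stop_gap=g,
            )
        )

    record = GenomeRecord(seq_id=genome.seq_id, sequence="".join(seq))
    paths = None
    if out_prefix is not None:
        paths = _write_dataset(record, genes, truth, out_prefix)
    return SyntheticDataset(record=record, genes=genes, truth=truth, paths=paths)


def _write_dataset(record, genes, truth, prefix) -> dict:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(prefix.suffix + ".fna"),
        "gff": prefix.with_suffix(prefix.suffix + ".gff"),
        "truth_bed": prefix.with_suffix(prefix.suffix + ".truth.bed"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{record.seq_id}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i : i + 70] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.seq_id} 1 {record.length}\n")
        for g in genes:
            fh.write(
                f"{record.seq_id}\tpefinder_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    with open(paths["truth_bed"], "w") as fh:
        for t in truth:
            fh.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.kind}\t0\t{t.strand}\n"
            )
    return paths


def read_truth_bed(path) -> list[TruthElement]:
    """Truth BED reader (column 4 carries the element kind)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                TruthElement(
                    seq_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    kind=cols[3],
                    strand=cols[5] if len(cols) > 5 else "+",
                )
            )
    return out


@dataclass
class RecoveryReport:
    recall: dict
    precision: Optional[float]
    confusion: dict
    n_truth: dict
    n_predictions: int
    matched: list


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def evaluate_recovery(
    predictions: Union[Sequence[PECandidate], str, Path],
    truth: Union[Sequence[TruthElement], str, Path],
) -> RecoveryReport:
    """Match predictions to implanted truth by >= 50% reciprocal overlap.

    Greedy best-overlap matching, each truth and each prediction used
    at most once. Recall per kind counts truth elements matched by a
    prediction of the SAME kind; a kind disagreement is recorded in the
    confusion table instead. Precision is matched predictions / total
    predictions (None when there are no predictions).
    """
    if isinstance(predictions, (str, Path)):
        import pandas as pd

        df = pd.read_csv(predictions, sep="\t")
        preds = [
            (row.seq_id, int(row.start) - 1, int(row.end), row.type)
            for row in df.itertuples()
        ]
    else:
        preds = [(c.seq_id, c.start, c.end, c.type) for c in predictions]
    if isinstance(truth, (str, Path)):
        truth = read_truth_bed(truth)

    pairs = []
    for ti, t in enumerate(truth):
        for pi, (sid, ps, pe, _kind) in enumerate(preds):
            if sid != t.seq_id:
                continue
            ov = _overlap(t.start, t.end, ps, pe)
            if ov <= 0:
                continue
            recip = min(ov / (t.end - t.start), ov / (pe - ps))
            if recip >= 0.5:
                pairs.append((recip, ti, pi))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _recip, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched.append((ti, pi))

    kinds = sorted({t.kind for t in truth})
    n_truth = {k: sum(1 for t in truth if t.kind == k) for k in kinds}
    confusion: dict[tuple[str, str], int] = {}
    hits = {k: 0 for k in kinds}
    for ti, pi in matched:
        tk, pk = truth[ti].kind, preds[pi][3]
        confusion[(tk, pk)] = confusion.get((tk, pk), 0) + 1
        if tk == pk:
            hits[tk] += 1
    recall = {k: (hits[k] / n_truth[k]) if n_truth[k] else None for k in kinds}
    precision = len(matched) / len(preds) if preds else None
    return RecoveryReport(
        recall=recall,
        precision=precision,
        confusion=confusion,
        n_truth=n_truth,
        n_predictions=len(preds),
        matched=matched,
    )
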