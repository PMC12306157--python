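"""Genome input/output and core sequence utilities.

Reads nucleotide FASTA and NCBI-style GFF3 annotation into the domain
model, writes candidate palindromic elements as TSV / BED6 / FASTA, and
provides the reverse-complement primitive on which palindromy is defined.

Coordinate conventions: everything in memory is 0-based half-open.
Conversions to the 1-based inclusive convention of GFF3 and the TSV
output, and to BED's 0-based half-open convention, happen only inside
the readers and writers in this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import PECandidate

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "GFFParseError",
    "read_fasta",
    "read_gff",
    "revcomp",
    "write_outputs",
]

_DNA = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGT = re.compile(r"[^ACGT]")

#: TSV column order of the candidate table (1-based inclusive coordinates).
TSV_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "strand",
    "type",
    "length",
    "sequence",
    "stem_len",
    "loop_len",
    "hairpin_energy",
    "tail_score",
    "upstream_gene",
    "dist_upstream",
    "downstream_gene",
    "dist_downstream",
    "within_15nt_of_stop",
]


class GFFParseError(ValueError):
    """Raised for malformed GFF3 rows; message names the offending line."""


@dataclass(frozen=True)
class GenomeRecord:
    """One chromosome or contig, normalized to the {A,C,G,T,N} alphabet."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"record {self.seq_id!r} contains non-normalized characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene/CDS interval; defines intergenic space and ORF distances.

    ``start``/``end`` are 0-based half-open. ``strand`` is ``+`` or ``-``;
    the strand-aware 3' end (the stop-codon side for a CDS) is ``end`` on
    ``+`` and ``start`` on ``-``.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "gene"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the strand-aware 3' boundary."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U to T, and replace anything else outside ACGT with N."""
    s = raw.upper().replace("U", "T")
    return _NON_ACGT.sub("N", s)


def revcomp(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Palindromy in the nucleic-acid sense means the two arms of an element
    are reverse complements of each other, so this is the primitive every
    seeding and extension step builds on.
    """
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (possibly multi-record) nucleotide FASTA into GenomeRecords.

    Sequences are uppercased, U is mapped to T, and any remaining
    non-ACGT character (ambiguity codes included) becomes N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = [
        GenomeRecord(seq_id=rec.id, sequence=normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def read_gff(path, feature_classes: Iterable[str] = ("gene",)) -> list[GeneFeature]:
    """Read gene features from a 9-column GFF3 file.

    Only rows whose type (column 3) is in ``feature_classes`` are kept.
    GFF 1-based inclusive coordinates become 0-based half-open. The gene
    identifier is taken from the ``ID=`` attribute, falling back to
    ``locus_tag=`` and then to a synthetic ``feat<N>``.
    """
    path = Path(path)
    wanted = set(feature_classes)
    if not wanted:
        raise ValueError("feature_classes must be nonempty")
    if not path.exists():
        raise FileNotFoundError(f"GFF file not found: {path}")

    feats: list[GeneFeature] = []
    synth = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            ftype = cols[2]
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GFFParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GFFParseError(f"line {lineno}: end ({end1}) < start ({start1})")
            strand = cols[6]
            if strand not in ("+", "-"):
                raise GFFParseError(f"line {lineno}: unknown strand {strand!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                synth += 1
                gene_id = f"feat{synth}"
            feats.append(
                GeneFeature(
                    seq_id=cols[0],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    feature_class=ftype if ftype in ("gene", "CDS") else "other",
                    gene_id=gene_id,
                )
            )
    return feats


def _sorted_candidates(candidates: list["PECandidate"]) -> list["PECandidate"]:
    return sorted(candidates, key=lambda c: (c.seq_id, c.start, c.end, c.strand))


def write_outputs(candidates: list["PECandidate"], prefix) -> dict[str, Path]:
    """Write the candidate table as ``<prefix>.tsv``, ``.bed`` and ``.fasta``.

    TSV coordinates are 1-based inclusive; BED6 is 0-based half-open with
    score ``round(-10 * hairpin_energy)`` clamped to [0, 1000]; FASTA
    headers are ``<seq_id>:<start>-<end>(<strand>)|<type>`` with the
    element sequence in its detected orientation. Rows are sorted by
    (seq_id, start, end, strand) in all three files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cands = _sorted_candidates(candidates)
    paths = {
        "tsv": prefix.with_suffix(prefix.suffix + ".tsv"),
        "bed": prefix.with_suffix(prefix.suffix + ".bed"),
        "fasta": prefix.with_suffix(prefix.suffix + ".fasta"),
    }

    with open(paths["tsv"], "w") as tsv:
        tsv.write("\t".join(TSV_COLUMNS) + "\n")
        for c in cands:
            row = [
                c.seq_id,
                str(c.start + 1),
                str(c.end),
                c.strand,
                c.type,
                str(c.end - c.start),
                c.sequence,
                str(c.stem_len),
                str(c.loop_len),
                f"{c.hairpin_energy:.1f}",
                f"{c.tail_score:.4f}",
                c.upstream_gene if c.upstream_gene is not None else "NA",
                str(c.dist_upstream) if c.dist_upstream is not None else "NA",
                c.downstream_gene if c.downstream_gene is not None else "NA",
                str(c.dist_downstream) if c.dist_downstream is not None else "NA",
                "true" if c.within_15nt_of_stop else "false",
            ]
            tsv.write("\t".join(row) + "\n")

    ordinals: dict[str, int] = {}
    with open(paths["bed"], "w") as bed:
        for c in cands:
            ordinals[c.type] = ordinals.get(c.type, 0) + 1
            score = min(1000, max(0, round(-10.0 * c.hairpin_energy)))
            bed.write(
                f"{c.seq_id}\t{c.start}\t{c.end}\t{c.type}_{ordinals[c.type]}"
                f"\t{score}\t{c.strand}\n"
            )

    with open(paths["fasta"], "w") as fa:
        for c in cands:
            fa.write(f">{c.seq_id}:{c.start + 1}-{c.end}({c.strand})|{c.type}\n")
            fa.write(c.sequence + "\n")

    return paths
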