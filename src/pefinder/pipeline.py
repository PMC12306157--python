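"""End-to-end candidate pipeline.

Orchestrates: read inputs → extract intergenic regions → scan both
orientations of every region → infer and score hairpins → structural
and energy filters → tail classification → gene-distance annotation →
cross-strand resolution and overlap deduplication → outputs and
summaries (totals, 1-nt length histogram, stop-codon proximity groups,
per-window strand densities).

Strand reporting: hairpins are orientation-symmetric but tails are not,
so each intergenic region is scanned in both orientations and an
element is reported on the strand in which its T-rich tail lies 3' of
the hairpin. When the two orientations of the same locus disagree (RIT
one way, REP the other) the RIT is kept; a REP seen identically both
ways is reported once, on '+'.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .genome_io import (
    GeneFeature,
    GenomeRecord,
    read_fasta,
    read_gff,
    revcomp,
    write_outputs,
)
from .hairpin_energy import EnergyModel, Hairpin, infer_structure, passes_energy, score_hairpin
from .intergenic import IntergenicRegion, extract_intergenic
from .palindrome_scan import ArmPair, ScanConfig, scan_sequence
from .tail_rit import TailModel, classify, tail_score

__all__ = [
    "PECandidate",
    "PipelineResult",
    "apply_structural_filters",
    "annotate",
    "dedup_overlaps",
    "resolve_orientations",
    "window_density",
    "partition_windows",
    "run_pipeline",
    "candidates_to_frame",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class PECandidate:
    """A classified palindromic element in genome coordinates (0-based half-open).

    ``sequence`` is the element in its detected orientation (reverse
    complement of the forward-strand slice for '-' elements).
    ``dist_stop`` is the gap to the 3' (stop-codon) end of the nearest
    same-strand upstream gene, when one exists.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    type: str
    sequence: str
    stem_len: int
    loop_len: int
    hairpin_energy: float
    tail_score: float
    upstream_gene: Optional[str] = None
    dist_upstream: Optional[int] = None
    downstream_gene: Optional[str] = None
    dist_downstream: Optional[int] = None
    within_15nt_of_stop: bool = False
    dist_stop: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("sequence length must equal end - start")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.type not in ("REP", "RIT"):
            raise ValueError("type must be REP or RIT")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PipelineResult:
    candidates: list[PECandidate]
    summary: dict
    table: pd.DataFrame
    output_paths: Optional[dict] = None


def apply_structural_filters(
    h: Hairpin, cfg: ScanConfig, model: EnergyModel = EnergyModel()
) -> bool:
    """Admissibility of a scored hairpin under the structural criteria.

    Requires: each arm within [min_palindrome, max_palindrome] nt; loop
    at most max_loop; at least min_stem paired positions; paired-stem /
    loop ratio at least min_stem_loop_ratio; whole element at least
    min_element_len nt; and the energy cutoff. All bounds inclusive.
    """
    p = h.arm_pair
    if not (cfg.min_palindrome <= p.left_len <= cfg.max_palindrome):
        return False
    if not (cfg.min_palindrome <= p.right_len <= cfg.max_palindrome):
        return False
    if h.loop_len > cfg.max_loop:
        return False
    if h.stem_pairs < cfg.min_stem:
        return False
    if h.stem_pairs < cfg.min_stem_loop_ratio * max(h.loop_len, 1) - _EPS:
        return False
    if p.outer_span < cfg.min_element_len:
        return False
    return passes_energy(h, model)


def _candidates_in_region(
    region: IntergenicRegion,
    genome: GenomeRecord,
    cfg: ScanConfig,
    energy_model: EnergyModel,
    tail_model: TailModel,
) -> list[PECandidate]:
    """Scan one intergenic region in both orientations."""
    fwd = genome.sequence[region.start : region.end]
    out: list[PECandidate] = []
    for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
        for pair in scan_sequence(seq, cfg):
            h = infer_structure(pair, seq)
            score_hairpin(h, energy_model)
            if not apply_structural_filters(h, cfg, energy_model):
                continue
            tail = seq[pair.right_end : pair.right_end + tail_model.window]
            tscore = tail_score(tail, tail_model)
            kind = classify(h, tail, tail_model)
            if strand == "+":
                g_start = region.start + pair.left_start
                g_end = region.start + pair.right_end
            else:
                g_start = region.start + (region.length - pair.right_end)
                g_end = region.start + (region.length - pair.left_start)
            out.append(
                PECandidate(
                    seq_id=region.seq_id,
                    start=g_start,
                    end=g_end,
                    strand=strand,
                    type=kind,
                    sequence=seq[pair.left_start : pair.right_end],
                    stem_len=pair.left_len,
                    loop_len=h.loop_len,
                    hairpin_energy=h.energy,
                    tail_score=tscore,
                )
            )
    return out


def _reciprocal_overlap(a: PECandidate, b: PECandidate) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / min(a.length, b.length)


def resolve_orientations(cands: list[PECandidate]) -> list[PECandidate]:
    """Resolve opposite-strand detections of the same hairpin locus.

    For overlapping (reciprocal overlap >= 50%) opposite-strand pairs:
    a RIT outcompetes a REP (the tail signal fixes the strand); two
    RITs keep the more T-rich tail ('+' on a tie). Identical-span
    REP/REP duplicates collapse later in :func:`dedup_overlaps` via its
    energy/leftmost/'+' tie-breaks.
    """
    cands = sorted(cands, key=_sort_key)
    drop: set[int] = set()
    for i, a in enumerate(cands):
        for j in range(i + 1, len(cands)):
            b = cands[j]
            if b.seq_id != a.seq_id or b.start >= a.end:
                break
            if a.strand == b.strand or _reciprocal_overlap(a, b) < 0.5:
                continue
            if a.type == b.type == "RIT":
                loser = j if (a.tail_score, a.strand) <= (b.tail_score, b.strand) else i
                drop.add(loser)
            elif a.type != b.type:
                drop.add(i if a.type == "REP" else j)
    return [c for n, c in enumerate(cands) if n not in drop]


def _sort_key(c: PECandidate) -> tuple:
    return (c.seq_id, c.start, c.end, c.strand)


def dedup_overlaps(cands: list[PECandidate]) -> list[PECandidate]:
    """Collapse same-type candidates overlapping > 50% of the shorter span.

    The lowest-energy candidate wins; ties go leftmost, then longest,
    then '+'. Different types never suppress each other here.
    """

    def better(a: PECandidate, b: PECandidate) -> PECandidate:
        ka = (a.hairpin_energy, a.start, -a.length, a.strand)
        kb = (b.hairpin_energy, b.start, -b.length, b.strand)
        return a if ka <= kb else b

    kept: list[PECandidate] = []
    for c in sorted(cands, key=_sort_key):
        merged = c
        survivors = []
        for k in kept:
            if (
                k.seq_id == merged.seq_id
                and k.type == merged.type
                and _reciprocal_overlap(k, merged) > 0.5
            ):
                merged = better(k, merged)
            else:
                survivors.append(k)
        survivors.append(merged)
        kept = survivors
    return sorted(kept, key=_sort_key)


def annotate(
    c: PECandidate,
    genes: list[GeneFeature],
    cfg: ScanConfig,
) -> Optional[PECandidate]:
    """Attach flanking-gene annotation; apply gene-distance rules.

    Upstream/downstream genes are the nearest on the forward axis
    regardless of strand; distances are gap sizes (0 = adjacent).
    ``within_15nt_of_stop`` is true when a SAME-strand gene has its
    stop-codon (3') end upstream of the element, in the element's
    reading direction, at a gap of at most 15 nt.

    Returns None when the candidate fails the configured gene-distance
    rules: ``max_gene_distance`` bounds the gap between the element and
    the nearest gene 5' end it faces; ``max_upstream_gene_distance``
    bounds the plain upstream gap. Elements with no qualifying gene are
    dropped unless ``cfg.keep_edge``.
    """
    mine = [g for g in genes if g.seq_id == c.seq_id]
    up = max(
        (g for g in mine if g.end <= c.start), key=lambda g: (g.end, g.start), default=None
    )
    down = min(
        (g for g in mine if g.start >= c.end), key=lambda g: (g.start, g.end), default=None
    )

    dist_up = c.start - up.end if up else None
    dist_down = down.start - c.end if down else None

    # strand-aware stop-codon proximity (transcriptional upstream)
    dist_stop: Optional[int] = None
    if c.strand == "+":
        g3 = max(
            (g for g in mine if g.strand == "+" and g.end <= c.start),
            key=lambda g: g.end,
            default=None,
        )
        if g3:
            dist_stop = c.start - g3.end
    else:
        g3 = min(
            (g for g in mine if g.strand == "-" and g.start >= c.end),
            key=lambda g: g.start,
            default=None,
        )
        if g3:
            dist_stop = g3.start - c.end

    if cfg.max_gene_distance is not None:
        # distance to the nearest gene 5' end the element faces
        d5_opts = []
        if down is not None:
            d5p = min(
                (g.start - c.end for g in mine if g.strand == "+" and g.start >= c.end),
                default=None,
            )
            if d5p is not None:
                d5_opts.append(d5p)
        if up is not None:
            d5m = min(
                (c.start - g.end for g in mine if g.strand == "-" and g.end <= c.start),
                default=None,
            )
            if d5m is not None:
                d5_opts.append(d5m)
        if not d5_opts:
            if not cfg.keep_edge:
                return None
        elif min(d5_opts) > cfg.max_gene_distance:
            return None

    if cfg.max_upstream_gene_distance is not None:
        if dist_up is None:
            if not cfg.keep_edge:
                return None
        elif dist_up > cfg.max_upstream_gene_distance:
            return None

    if up is None and down is None and not cfg.keep_edge:
        return None

    return replace(
        c,
        upstream_gene=up.gene_id if up else None,
        dist_upstream=dist_up,
        downstream_gene=down.gene_id if down else None,
        dist_downstream=dist_down,
        within_15nt_of_stop=dist_stop is not None and dist_stop <= 15,
        dist_stop=dist_stop,
    )


def partition_windows(length: int, window: int = 100_000) -> list[tuple[int, int]]:
    """Consecutive windows covering [0, length); the last may be short."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return [(s, min(s + window, length)) for s in range(0, length, window)]


def window_density(
    cands: list[PECandidate],
    window: int = 100_000,
    genome_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-(record, window, strand, type) candidate counts.

    Each candidate is counted in the window containing its start
    (1-based window index). When ``genome_lengths`` is given, every
    window of each record appears, zero-filled, so the frame describes
    the full partition (e.g. a 4,641,652 nt chromosome at 100 kb gives
    47 windows, the last of 41,652 bp).
    """
    rows = []
    if genome_lengths:
        for seq_id, length in genome_lengths.items():
            for idx, (ws, we) in enumerate(partition_windows(length, window), start=1):
                for strand in ("+", "-"):
                    for kind in ("REP", "RIT"):
                        rows.append(
                            {
                                "seq_id": seq_id,
                                "window": idx,
                                "window_start": ws,
                                "window_end": we,
                                "strand": strand,
                                "type": kind,
                                "count": 0,
                            }
                        )
    df = pd.DataFrame(
        rows,
        columns=["seq_id", "window", "window_start", "window_end", "strand", "type", "count"],
    )
    counts: dict[tuple, int] = {}
    for c in cands:
        key = (c.seq_id, c.start // window + 1, c.strand, c.type)
        counts[key] = counts.get(key, 0) + 1
    if df.empty:
        df = pd.DataFrame(
            [
                {
                    "seq_id": k[0],
                    "window": k[1],
                    "window_start": (k[1] - 1) * window,
                    "window_end": None,
                    "strand": k[2],
                    "type": k[3],
                    "count": v,
                }
                for k, v in sorted(counts.items())
            ],
            columns=["seq_id", "window", "window_start", "window_end", "strand", "type", "count"],
        )
    else:
        for k, v in counts.items():
            mask = (
                (df["seq_id"] == k[0])
                & (df["window"] == k[1])
                & (df["strand"] == k[2])
                & (df["type"] == k[3])
            )
            df.loc[mask, "count"] = v
    return df.sort_values(["seq_id", "window", "strand", "type"]).reset_index(drop=True)


def candidates_to_frame(cands: list[PECandidate]) -> pd.DataFrame:
    """Candidate list as a DataFrame (internal 0-based coordinates)."""
    return pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "type": c.type,
                "length": c.length,
                "sequence": c.sequence,
                "stem_len": c.stem_len,
                "loop_len": c.loop_len,
                "hairpin_energy": c.hairpin_energy,
                "tail_score": c.tail_score,
                "upstream_gene": c.upstream_gene,
                "dist_upstream": c.dist_upstream,
                "downstream_gene": c.downstream_gene,
                "dist_downstream": c.dist_downstream,
                "within_15nt_of_stop": c.within_15nt_of_stop,
            }
            for c in cands
        ],
        columns=[
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
        ],
    )


def summarize(
    cands: list[PECandidate],
    genome_lengths: dict[str, int],
    window: int = 100_000,
) -> dict:
    """Totals, 1-nt length histogram, stop-proximity groups, densities."""
    reps = [c for c in cands if c.type == "REP"]
    rits = [c for c in cands if c.type == "RIT"]
    hist: dict[int, int] = {}
    for c in cands:
        hist[c.length] = hist.get(c.length, 0) + 1
    with_upstream = [c for c in reps if c.dist_stop is not None]
    group1 = sum(1 for c in with_upstream if c.dist_stop <= 15)
    return {
        "n_total": len(cands),
        "n_rep": len(reps),
        "n_rit": len(rits),
        "length_hist": dict(sorted(hist.items())),
        "group1_reps": group1,
        "group2_reps": len(with_upstream) - group1,
        "density": window_density(cands, window, genome_lengths),
    }


def run_pipeline(
    fasta,
    gff,
    cfg: Optional[ScanConfig] = None,
    energy_model: Optional[EnergyModel] = None,
    tail_model: Optional[TailModel] = None,
    out_prefix=None,
    feature_classes: Iterable[str] = ("gene",),
    window: int = 100_000,
) -> PipelineResult:
    """Run the full discovery workflow on a genome + annotation.

    Deterministic: identical inputs and configuration give a
    byte-identical candidate table. When no row of the requested
    feature classes exists in the annotation, CDS rows are used
    instead (the most conservative definition of extragenic space
    still available).
    """
    cfg = cfg or ScanConfig()
    energy_model = energy_model or EnergyModel()
    tail_model = tail_model or TailModel()

    t0 = time.perf_counter()
    genomes = read_fasta(fasta)
    genes = read_gff(gff, feature_classes)
    if not genes and set(feature_classes) != {"CDS"}:
        logger.info("no %s rows in annotation; falling back to CDS", set(feature_classes))
        genes = read_gff(gff, ("CDS",))
    logger.info(
        "loaded %d record(s), %d gene feature(s) [%.2fs]",
        len(genomes),
        len(genes),
        time.perf_counter() - t0,
    )

    all_cands: list[PECandidate] = []
    for genome in genomes:
        t1 = time.perf_counter()
        regions = extract_intergenic(genes, genome, min_len=cfg.min_element_len)
        raw: list[PECandidate] = []
        for region in regions:
            raw.extend(
                _candidates_in_region(region, genome, cfg, energy_model, tail_model)
            )
        resolved = resolve_orientations(raw)
        annotated = [
            a for c in resolved if (a := annotate(c, genes, cfg)) is not None
        ]
        deduped = dedup_overlaps(annotated)
        logger.info(
            "%s: %d regions -> %d raw -> %d annotated -> %d final [%.2fs]",
            genome.seq_id,
            len(regions),
            len(raw),
            len(annotated),
            len(deduped),
            time.perf_counter() - t1,
        )
        all_cands.extend(deduped)

    all_cands.sort(key=_sort_key)
    lengths = {g.seq_id: g.length for g in genomes}
    summary = summarize(all_cands, lengths, window)
    table = candidates_to_frame(all_cands)
    paths = write_outputs(all_cands, out_prefix) if out_prefix is not None else None
    return PipelineResult(
        candidates=all_cands, summary=summary, table=table, output_paths=paths
    )
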