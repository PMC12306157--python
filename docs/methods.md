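# Methods

## Model

`pefinder` treats a palindromic element as a DNA stem-loop: two arms
that are (approximately) reverse complements of each other separated
by a short unpaired loop. Elements are sought only in intergenic
space — the complement of the merged, strand-agnostic gene cover —
because the repeats of interest are extragenic by definition.
Chromosomes are handled as linear sequences; no wrap-around region is
formed between the last and first gene of a (biologically circular)
chromosome, which matches the linear 100-kb sectioning used in the
density summaries.

Detection is seed-and-extend. Every intergenic region is decomposed
into overlapping k-mers (k = 6); a pair of positions (i, j) seeds a
stem when the k-mer at j is the exact reverse complement of the k-mer
at i and the outer span (j+k) − i is at most 50 bp. Seeds grow inward
and outward one base pair at a time while the added pair is
Watson-Crick or a G·T wobble; extension stops at the first non-pairing
position. Stems separated by at most 2 nt on both arms are then
assembled into a single imperfect stem, repeating to a fixed point,
with duplicate and arm-wise-contained results removed.

Candidate hairpins are scored with an additive energy model
(kcal/mol): G·C −2.3, A·T −0.9, G·T +1.3, +3.5 per mismatched pair,
+6.0 per one-sided gap, plus a linear loop term 1·(loop − 2). A
candidate survives when its energy is ≤ −0.2 and it satisfies the
structural filters (arm 5–32 nt, loop ≤ 11 nt, ≥ 1 stem pair,
paired-stem/loop ratio ≥ 0.2, whole element ≥ 10 nt — the shortest
sequence that can fold into any hairpin at all). All thresholds are
inclusive; "cutoff" values with one decimal are summed in integer
tenths so classification near a boundary is bit-stable.

Surviving hairpins are classified by the composition of the ≤ 15 nt
immediately 3′ of the stem: the tail score −Σ_{i=1..L} Π_{j=1..i}
w(x_j), with w(T) = 0.9 and w(other) = 0.6 and x₁ the base nearest the
hairpin, reaches ≈ −7.15 for 15×T and ≈ −1.50 for 15×A; scores ≤ −2.5
label the element a Rho-independent terminator (RIT), anything else a
putative REP. The functional form is a geometric-weight reconstruction
chosen so that (a) only the two published weights appear, (b) thymines
nearest the hairpin dominate, and (c) the all-T/all-A extremes fall on
the expected sides of the −2.5 threshold; it is held behind a single
function (`tail_score`) so an alternative form can be swapped without
touching classification.

## Strand handling

A hairpin is the same structure read from either strand, but its tail
is not. Both orientations of every intergenic region are scanned, and
an element is reported on the strand whose tail supports it: when
opposite-strand detections of the same locus (reciprocal overlap
≥ 50 %) disagree — RIT one way, REP the other — the RIT is kept; two
RITs keep the more T-rich tail; a REP detected identically both ways
is reported once, on "+". Remaining same-type candidates overlapping
by more than half of the shorter span collapse to the lowest-energy
one (ties: leftmost, then longest, then "+"). Note that G·T wobbles
break the symmetry (a G·T read on one strand is an unpairable A·C on
the other), so the two orientations of a wobble-containing stem can
genuinely differ in extent and energy.

## Mismatches vs gaps in assembled stems

Extension stops at the first non-pair, so mismatches cannot appear
inside an extended stem; they arise only where two stems are stitched
together. When the interruption has equal length on both arms, the
facing bases are counted as mismatched pairs (+3.5 each); only the
one-sided excess is a gap (+6.0 per inserted base). This convention
keeps both penalty classes of the energy model reachable and follows
the usual hairpin-alignment reading in which opposing unpaired bases
form an internal mismatch and a single-sided insertion forms a bulge.

## Gene-distance rules and grouping

Two independent proximity rules control which candidates are kept.
The default bounds the gap between the element and the nearest gene 5′
end it faces (≤ 200 nt), reflecting the regulatory context in which
these elements are usually interpreted. For exhaustive whole-genome
surveys, `ScanConfig.mg1655()` instead disables that rule and bounds
the plain gap to the nearest upstream gene at 6,200 nt — just above
the longest intergenic spacer in *E. coli* K-12 MG1655 (6,176 bp) —
so every intergenic region remains reachable. REPs with a same-strand
upstream gene are split at the stop-codon distance: ≤ 15 nt (group 1,
the putative translational regulators, matching the known requirement
that ribosome-stalling REPs sit within 15 nt of the stop codon) versus
≥ 16 nt (group 2).

## Synthetic data generator

`make_genome` draws an i.i.d. chromosome at a chosen GC fraction;
`implant` splices perfect palindromes (arm + loop + reverse-complement
arm) into intergenic gaps of a regular gene layout and writes
FASTA/GFF3/truth-BED. Defaults define the "clean" fixture used by the
tests and the acceptance script: a 100-kb, 50 %-GC chromosome with 80
genes (900 nt genes, 220 nt gaps), 20 REP implants and 10 RIT implants
with 8-nt arms at GC fraction 0.8, 4-nt loops, and 12×T tails on the
RITs, placed 20–40 nt downstream of a stop codon. The 220-nt gap keeps
every implant within 200 nt of the next gene's 5′ end, i.e. inside the
default proximity rule. Two constructions keep fixture kinds
unambiguous by design: flanking bases at the implant boundaries are
pinned so the stem cannot extend outward in either orientation (the
boundary pairs are invalid on both strands), and the 15-nt flanks that
could be read as tails are redrawn if they would score within 0.2 of
the −2.5 tail cutoff in either direction.

What the generator does **not** emulate: real genomes have skewed
composition, repeat families with shared consensus motifs, operons,
and RNA-level context. Passing the recovery tests therefore shows the
scanner finds and classifies well-formed stem-loops at realistic
densities and noise — not that its candidate lists on a real genome
are complete or free of false positives. Chance palindromes in random
background are expected and intentional: precision on synthetic
fixtures (~0.4) reflects that background, which is why recovery is
measured as recall on truth loci plus kind accuracy.

## Numerical and procedural choices

- Coordinates are 0-based half-open everywhere internally; GFF/TSV
  (1-based inclusive) and BED (0-based half-open) conversions happen
  only at I/O boundaries.
- Ambiguity codes other than N become N on load; k-mers containing N
  never seed, and N never pairs.
- The 50-bp seed threshold is measured on the outer span by default; a
  `start` mode (distance between arm start positions) is available.
- The loop penalty applies literally even for 0–2 nt loops (where it
  is ≤ 0); structural filters, not the energy term, govern
  admissibility there.
- Deduplication thresholds: > 50 % of the shorter span for same-type
  collapse, ≥ 50 % reciprocal overlap for cross-strand resolution and
  for truth matching in recovery evaluation (greedy, best overlap
  first, each element matched at most once).
- Determinism: no randomness anywhere in the detection path; the
  generator uses one seeded RNG stream per call. Identical inputs give
  byte-identical outputs.
- Problem sizes in the test-suite and acceptance runs: 100-kb fixture
  with 30 implants for recovery; 200 random sequences up to 2 kb for
  the seed-oracle equivalence check; these sizes exercise every code
  path while keeping a full run to seconds.

## Known limitations

- The energy model is the simple additive scheme above, not
  nearest-neighbour thermodynamics; energies are comparable within a
  run but are not folding free energies.
- Mismatches inside a stem are only representable where assembly
  joined two seeds; a single isolated mismatch flanked by fewer than
  k = 6 exact pairs on either side produces no second seed and the
  shorter perfect stem is reported instead.
- The whole-genome survey of a real assembly reproduces published
  catalogues only approximately: extension, assembly and
  deduplication details differ between implementations, so totals are
  compared at a tolerance (≤ 15 % in the regression test) rather than
  exactly.
- Genome records are processed independently; elements spanning contig
  boundaries (or the origin of a circular chromosome) are not found.
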