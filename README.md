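# pefinder

Discovery and classification of palindromic elements in bacterial and
archaeal genomes.

Intergenic DNA in many prokaryotes is littered with short palindromes
that fold into stem-loop structures. Two classes dominate:
**repetitive extragenic palindromic elements (REPs)** — ~10–70 nt
repeats implicated in mRNA stability and translational control — and
**Rho-independent terminators (RITs)** — hairpins immediately followed
by a thymine/uridine-rich 3′ tail that release RNA polymerase.
`pefinder` finds both classes in an annotated genome (FASTA + GFF3)
and tells them apart, for microbiologists and comparative genomicists
who want a genome-wide catalogue of these elements without manual
curation.

## Method

1. **Intergenic extraction** — genes from both strands are merged and
   complemented; only intergenic intervals are scanned.
2. **Palindrome seeding** — each region is decomposed into k-mers
   (k = 6); exact reverse-complementary k-mer pairs within a 50 bp
   span seed candidate stems.
3. **Extension and assembly** — seeds grow in both directions while
   the added pair is Watson-Crick (A·T, G·C) or G·T wobble; stems
   interrupted by ≤ 2 nt are stitched into one imperfect stem.
4. **Energy scoring** — an additive hairpin energy
   `E = Σ e(pair) + 1·(loop − 2)` with e(G·C) = −2.3, e(A·T) = −0.9,
   e(G·T) = +1.3, mismatch +3.5, gap +6.0 (kcal/mol); hairpins pass at
   E ≤ −0.2. Structural filters: arm 5–32 nt, loop ≤ 11 nt,
   stem/loop ≥ 0.2, element ≥ 10 nt.
5. **Tail classification** — the tail score over the ≤ 15 nt 3′ of the
   hairpin, `S = −Σᵢ Πⱼ≤ᵢ w(xⱼ)` with w(T) = 0.9 and w(other) = 0.6,
   classifies the element as RIT when S ≤ −2.5, REP otherwise.
6. **Annotation** — distances to flanking ORFs, a flag for REPs within
   15 nt of an upstream stop codon (the putative translational-control
   class), per-100-kb strand densities.

A synthetic-genome generator (`make_genome` / `implant`) produces
annotated chromosomes with implanted REPs and RITs plus ground truth,
so the whole workflow is testable end to end, and
`similarity_score` / `similarity_matrix` summarize cross-group
consensus-motif similarity as Nab/(Na+Nb) from external motif-matching
output.

## Worked example

```python
import pefinder as pf
from pefinder.palindrome_scan import ScanConfig

seq = "AA" + "GCCGGAT" + "TTTT" + "ATCCGGC" + "AA"
(pair,) = pf.scan_sequence(seq, ScanConfig())
hairpin = pf.infer_structure(pair, seq)
print(pf.score_hairpin(hairpin))        # -11.3
print(pf.tail_score("T" * 12))          # -6.458...
print(pf.classify(hairpin, "T" * 12))   # RIT
```

The 7-pair stem (5 G·C, 2 A·T) around a 4-nt loop scores
5×(−2.3) + 2×(−0.9) + (4−2) = −11.3 kcal/mol — a stable hairpin — and
the 12×T tail scores −6.46, well below the −2.5 cutoff, so this
element is called a Rho-independent terminator. Running
`examples/discover_in_synthetic_genome.py` prints

```
candidates: 81 (55 REP, 26 RIT)
element lengths: 12-30 nt
recall REP: 1.00  RIT: 1.00
precision: 0.37
```

all 30 implanted elements are recovered with the correct kind; the
extra candidates are chance palindromes in the random background, the
same reason a real genome yields thousands of calls.

From a shell, the same pipeline is:

```bash
pefinder simulate --length 100000 --seed 1 --out-prefix sim
pefinder predict --fasta sim.fna --gff sim.gff --out-prefix pred
pefinder summary --tsv pred.tsv
```

`predict` writes the candidate table as TSV (1-based coordinates,
energies, tail scores, ORF distances), BED6 and FASTA. For an
exhaustive survey of a real genome such as MG1655, disable the 200-nt
5′-distance default and bound the upstream gap instead:
`--max-gene-distance -1 --max-upstream-distance 6200`.

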