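"""Similarity between consensus-motif groups from match counts.

Motif discovery and cross-matching are done by external tools; given
their tabulated output (unique motif counts Na, Nb per group and
matched motifs Nab per pair), compute the pairwise similarity
Nab / (Na + Nb) and each group's total significant matches.
"""

import tempfile
from pathlib import Path

import pefinder as pf
from pefinder.motif_similarity import read_pairs_tsv

PAIRS = """\
group_a\tgroup_b\tNa\tNb\tNab
motif1\tmotif2\t12\t8\t4
motif1\tmotif3\t12\t5\t0
motif2\tmotif3\t8\t5\t2
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "pairs.tsv"
    path.write_text(PAIRS)
    groups = read_pairs_tsv(path)

matrix, totals = pf.similarity_matrix(groups)
print("similarity matrix (0 = disjoint, 0.5 = identical):")
print(matrix.round(3).to_string())
print("\ntotal significant matches per group:")
print(totals.to_string())

# motif1 and motif2 share 4 of their 20 combined motifs (score 0.2);
# motif3 overlaps only motif2. The diagonal is 0.5 by convention.
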