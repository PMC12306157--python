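"""Score one stem-loop by hand: seeding, extension, energy, tail.

Walks a 22-nt sequence with a GC-rich palindrome through each stage of
the method and prints the intermediate objects, ending with the
REP-vs-RIT call for two alternative 3' tails.
"""

import pefinder as pf
from pefinder.palindrome_scan import ScanConfig

seq = "AA" + "GCCGGAT" + "TTTT" + "ATCCGGC" + "AA"
print("sequence:", seq)

(pair, *_) = pf.scan_sequence(seq, ScanConfig())
print(f"arms: [{pair.left_start},{pair.left_end}) / "
      f"[{pair.right_start},{pair.right_end}), loop {pair.loop_len} nt")

hairpin = pf.infer_structure(pair, seq)
energy = pf.score_hairpin(hairpin)
print("stem pair classes:", " ".join(hairpin.stem))
print(f"energy: {energy} kcal/mol  (5 G-C at -2.3, 2 A-T at -0.9, loop 4-2)")

for tail in ("T" * 12, "ACGACGACGACG"):
    score = pf.tail_score(tail)
    call = pf.classify(hairpin, tail)
    print(f"tail {tail}: score {score:.3f} -> {call}")

# A T-rich tail drives the tail score below the -2.5 cutoff, so the
# same hairpin is a Rho-independent terminator with one tail and a
# repetitive extragenic palindrome candidate with the other.
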