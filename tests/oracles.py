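"""Independent brute-force oracles used by the test suite."""

from pefinder.genome_io import revcomp


def brute_force_seed_pairs(seq: str, k: int, max_span: int) -> set[tuple[int, int]]:
    """All (i, j) with kmer(j) == revcomp(kmer(i)), i + k <= j and outer
    span (j + k) - i <= max_span, by direct enumeration of the
    span-feasible j range for every i."""
    out = set()
    n = len(seq)
    for i in range(n - k + 1):
        a = seq[i : i + k]
        if "N" in a:
            continue
        target = revcomp(a)
        for j in range(i + k, min(i + max_span - k, n - k) + 1):
            b = seq[j : j + k]
            if "N" not in b and b == target:
                out.add((i, j))
    return out
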