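"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation's algorithms: the alignment
oracle is a plain cubic dynamic program that scores every possible gap
length at every cell instead of carrying affine gap states, and the
frame oracle decides frameshift vs in-frame by translating and comparing
downstream peptides rather than by arithmetic on indel lengths.
"""

from itertools import product

from Bio.Seq import Seq

NEG = float("-inf")


def brute_affine_score(q, r, match=2, mismatch=-3, gap_open=-8, gap_extend=-1):
    """Global alignment score by cubic DP; a gap of length k costs
    gap_open + gap_extend * (k - 1). No affine state machinery."""

    def gap(k):
        return gap_open + gap_extend * (k - 1)

    n, m = len(q), len(r)
    G = [[NEG] * (m + 1) for _ in range(n + 1)]
    G[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = NEG
            if i > 0 and j > 0:
                s = match if (q[i - 1] == r[j - 1] and q[i - 1] != "N") else mismatch
                prev = G[i - 1][j - 1]
                if prev > NEG:
                    best = prev + s
            row = G[i]
            for k in range(1, j + 1):
                cand = row[j - k]
                if cand > NEG:
                    cand = cand + gap(k)
                    if cand > best:
                        best = cand
            for k in range(1, i + 1):
                cand = G[i - k][j]
                if cand > NEG:
                    cand = cand + gap(k)
                    if cand > best:
                        best = cand
            G[i][j] = best
    return G[n][m]


def downstream_frame_differs(ref, mutant, tail_codons=4):
    """Frame oracle: translate both sequences from position 0 and compare
    the peptide encoded by the last ``tail_codons`` codons."""

    def tail(seq):
        trimmed = seq[: len(seq) - len(seq) % 3]
        prot = str(Seq(trimmed).translate())
        return prot[-tail_codons:]

    return tail(ref) != tail(mutant)
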