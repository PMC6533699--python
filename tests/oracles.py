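"""Independent reference implementations used only as test oracles.

Deliberately naive: the alignment oracle is a Waterman-Smith-Beyer style
dynamic programme with an explicit inner loop over gap lengths (no affine
three-state shortcut), and the ORF oracle is a per-frame segment scan
built on Biopython's translation. They share no code with the package
paths they check.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _sub(a: str, b: str) -> float:
    return _BLOSUM62[a][b]


def sw_score(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score; a length-k gap costs open + k*extend."""
    nq, ns = len(q), len(s)
    H = [[0.0] * (ns + 1) for _ in range(nq + 1)]
    best = 0.0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            cand = max(0.0, H[i - 1][j - 1] + _sub(q[i - 1], s[j - 1]))
            for k in range(1, i + 1):
                cand = max(cand, H[i - k][j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                cand = max(cand, H[i][j - k] - (gap_open + k * gap_extend))
            H[i][j] = cand
            best = max(best, cand)
    return int(round(best))


def nw_score(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal global alignment score with end gaps penalised."""
    nq, ns = len(q), len(s)
    NEG = float("-inf")
    D = [[NEG] * (ns + 1) for _ in range(nq + 1)]
    D[0][0] = 0.0
    for i in range(nq + 1):
        for j in range(ns + 1):
            if i == j == 0:
                continue
            cand = NEG
            if i and j:
                cand = D[i - 1][j - 1] + _sub(q[i - 1], s[j - 1])
            for k in range(1, i + 1):
                v = D[i - k][j] - (gap_open + k * gap_extend)
                cand = max(cand, v)
            for k in range(1, j + 1):
                v = D[i][j - k] - (gap_open + k * gap_extend)
                cand = max(cand, v)
            D[i][j] = cand
    return int(round(D[nq][ns]))


def nw_matches(q: str, s: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Number of identical aligned pairs in the optimal global alignment.

    Among co-optimal alignments, the one maximising matches is chosen (the
    quantity the identity statistic depends on is then well defined).
    """
    nq, ns = len(q), len(s)
    NEG = float("-inf")
    # (score, matches) per cell, lexicographic maximum
    D = [[(NEG, 0)] * (ns + 1) for _ in range(nq + 1)]
    D[0][0] = (0.0, 0)
    for i in range(nq + 1):
        for j in range(ns + 1):
            if i == j == 0:
                continue
            best = (NEG, 0)
            if i and j and D[i - 1][j - 1][0] > NEG:
                sc = D[i - 1][j - 1][0] + _sub(q[i - 1], s[j - 1])
                m = D[i - 1][j - 1][1] + (1 if q[i - 1] == s[j - 1] else 0)
                best = max(best, (sc, m))
            for k in range(1, i + 1):
                prev = D[i - k][j]
                if prev[0] > NEG:
                    best = max(best, (prev[0] - (gap_open + k * gap_extend), prev[1]))
            for k in range(1, j + 1):
                prev = D[i][j - k]
                if prev[0] > NEG:
                    best = max(best, (prev[0] - (gap_open + k * gap_extend), prev[1]))
            D[i][j] = best
    return D[nq][ns][1]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_frame(seq: str, offset: int) -> str:
    usable = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
    return str(Seq(usable).translate())


def scan_orfs(seq: str, min_aa: int) -> set[tuple]:
    """All ORFs of a contig as (strand, offset, start, end, protein,
    partial5, partial3) tuples, forward-strand half-open coordinates.

    Rules: a complete ORF runs from the first ATG of a stop-delimited
    segment through the stop; the leading segment without an ATG yields a
    5'-partial from the frame start; a trailing ATG without a stop yields a
    3'-partial; a frame without either is one both-ends-partial fragment.
    """
    L = len(seq)
    out: set[tuple] = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for off in range(3):
            if L - off < 3:
                continue
            prot = translate_frame(s, off)
            pos = 0
            for i, seg in enumerate(prot.split("*")):
                first = pos == 0
                has_stop = pos + len(seg) < len(prot)
                m = seg.find("M")
                rec = None
                if m != -1:
                    p0, p1 = pos + m, pos + len(seg)
                    rec = (p0, p1, False, not has_stop)
                elif first and seg:
                    rec = (pos, pos + len(seg), True, not has_stop)
                if rec is not None:
                    p0, p1, pa5, pa3 = rec
                    if p1 - p0 >= min_aa:
                        w0 = off + 3 * p0
                        w1 = off + 3 * (p1 + 1) if has_stop else off + 3 * p1
                        if strand == "+":
                            start, end = w0, w1
                        else:
                            start, end = L - w1, L - w0
                        out.add((strand, off, start, end, prot[p0:p1], pa5, pa3))
                pos += len(seg) + 1
    return out
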