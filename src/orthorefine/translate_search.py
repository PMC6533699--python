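"""Translated local homology search of proteins against nucleotide contigs.

A protein query is aligned with Smith-Waterman (affine gaps, BLOSUM62 by
default) against all six reading-frame translations of every contig, and
each hit is scored with Karlin-Altschul statistics: the bitscore is
(lambda * S - ln K) / ln 2 for raw score S, and the expected number of
chance hits is E = m * n * 2**(-bitscore) for query length m and database
size n. The gapped BLOSUM62/11/1 parameters lambda = 0.267, K = 0.041 are
used; a length-k gap costs gap_open + k * gap_extend.

Stop codons in translated frames take part in the alignment through the
matrix's ``*`` column (-4 against residues, +1 against ``*``); frames are
not split at stops. Subject coordinates of hits are reported on the
forward strand of the contig, 1-based inclusive, with sstart > send on the
minus strand (the tabular-format convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import NucRecord, ProtRecord, reverse_complement, translate

logger = logging.getLogger("orthorefine")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment and Karlin-Altschul scoring parameters.

    Defaults are the published gapped BLOSUM62 values with BLAST's default
    gap penalties (open 11, extend 1).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


DEFAULT_PARAMS = ScoringParams()
DEFAULT_EVALUE = 1e-4


def _make_aligner(params: ScoringParams, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    try:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {params.matrix!r}") from exc
    # First gap position costs open+extend, later ones extend each, so a
    # length-k gap costs gap_open + k*gap_extend (the BLAST convention).
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass(frozen=True)
class FrameTranslation:
    """One of a contig's six reading-frame translations.

    Minus-strand translations are of the reverse complement; their protein
    coordinates map back to intervals on the forward strand.
    """

    contig_id: str
    strand: str  # '+' or '-'
    offset: int  # 0, 1 or 2
    prot: str
    contig_len: int

    def nuc_interval(self, p0: int, p1: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval (0-based half-open) coding for
        protein positions [p0, p1)."""
        if self.strand == "+":
            return (self.offset + 3 * p0, self.offset + 3 * p1)
        return (
            self.contig_len - self.offset - 3 * p1,
            self.contig_len - self.offset - 3 * p0,
        )


@dataclass(frozen=True)
class Hsp:
    """A high-scoring segment pair between a query and a subject.

    In forward (tblastn-style) searches the query is a protein and the
    subject a contig: qstart <= qend are 1-based protein positions and
    sstart/send are forward-strand nucleotides with sstart > send on the
    minus strand. Reverse (blastx-style) searches swap the roles: query
    coordinates are nucleotides on the contig, subject coordinates protein.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: int = 0
    strand: str = "+"
    frame_offset: int = 0


def six_frame_translate(contig: NucRecord) -> list[FrameTranslation]:
    """All six reading-frame translations of a contig (3 offsets x 2 strands)."""
    if len(contig.seq) < 3:
        logger.warning("contig %s shorter than one codon; no frames", contig.id)
        return []
    frames = []
    rc = reverse_complement(contig.seq)
    for strand, seq in (("+", contig.seq), ("-", rc)):
        for offset in range(3):
            if len(seq) - offset < 3:
                continue
            frames.append(
                FrameTranslation(
                    contig_id=contig.id,
                    strand=strand,
                    offset=offset,
                    prot=translate(seq, offset),
                    contig_len=len(contig.seq),
                )
            )
    return frames


def local_align(
    q: str, s: str, params: ScoringParams = DEFAULT_PARAMS
) -> tuple[int, str, str, int, int, int, int]:
    """Optimal Smith-Waterman local alignment of two protein strings.

    Returns ``(raw_score, aligned_q, aligned_s, qstart, qend, sstart, send)``
    with 0-based half-open coordinates. A raw score of 0 means no
    positive-scoring local alignment exists; the aligned strings are then
    empty.
    """
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(params, "local")
    score = aligner.score(q, s)
    if score <= 0:
        return (0, "", "", 0, 0, 0, 0)
    aln = aligner.align(q, s)[0]
    qa, sa = aln[0], aln[1]
    qblocks, sblocks = aln.aligned
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    s0, s1 = int(sblocks[0][0]), int(sblocks[-1][1])
    return (int(round(score)), qa, sa, q0, q1, s0, s1)


def bitscore(raw_score: float, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Bitscore of a raw alignment score: (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    return (params.lam * raw_score - math.log(params.k)) / LN2


def evalue(bits: float, query_len: int, db_size: int) -> float:
    """Expected chance hits in a search space of query_len * db_size."""
    if query_len <= 0 or db_size <= 0:
        raise ValueError("query length and database size must be positive")
    return query_len * db_size * math.pow(2.0, -bits)


def _alignment_stats(qa: str, sa: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, align_len) of a gapped pair."""
    matches = mismatches = gap_opens = 0
    in_gap = False
    for a, b in zip(qa, sa):
        if a == "-" or b == "-":
            if not in_gap:
                gap_opens += 1
                in_gap = True
        else:
            in_gap = False
            if a == b:
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gap_opens, len(qa)


def _sort_hsps(hsps: list[Hsp]) -> list[Hsp]:
    return sorted(hsps, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def search(
    query: ProtRecord,
    contigs: Sequence[NucRecord],
    params: ScoringParams = DEFAULT_PARAMS,
    evalue_cutoff: float = DEFAULT_EVALUE,
    frames: Sequence[FrameTranslation] | None = None,
) -> list[Hsp]:
    """Translated search of a protein query against a contig database.

    The single best local alignment per (contig, strand, frame) is scored,
    hits with E-value above the cutoff are dropped, and the rest returned
    sorted by (bitscore desc, evalue asc, subject id asc). Pre-computed
    ``frames`` may be supplied to amortise six-frame translation across
    repeated searches of the same database.

    Subject coordinates are converted from frame protein space to 1-based
    forward-strand nucleotide positions.
    """
    if not contigs:
        raise ValueError("empty contig database")
    if frames is None:
        frames = [f for c in contigs for f in six_frame_translate(c)]
    db_size = sum(len(f.prot) for f in frames)
    if db_size == 0:
        return []
    qlen = len(query.seq)
    aligner = _make_aligner(params, "local")
    hsps: list[Hsp] = []
    for ft in frames:
        raw = aligner.score(query.seq, ft.prot)
        if raw <= 0:
            continue
        bits = bitscore(raw, params)
        ev = evalue(bits, qlen, db_size)
        if ev > evalue_cutoff:
            continue
        raw_i, qa, sa, q0, q1, s0, s1 = local_align(query.seq, ft.prot, params)
        matches, mismatches, gap_opens, align_len = _alignment_stats(qa, sa)
        n0, n1 = ft.nuc_interval(s0, s1)
        if ft.strand == "+":
            sstart, send = n0 + 1, n1
        else:
            sstart, send = n1, n0 + 1
        hsps.append(
            Hsp(
                query_id=query.id,
                subject_id=ft.contig_id,
                pct_identity=round(100.0 * matches / align_len, 2),
                align_len=align_len,
                mismatches=mismatches,
                gap_opens=gap_opens,
                qstart=q0 + 1,
                qend=q1,
                sstart=sstart,
                send=send,
                evalue=ev,
                bitscore=round(bits, 2),
                raw_score=raw_i,
                strand=ft.strand,
                frame_offset=ft.offset,
            )
        )
    return _sort_hsps(hsps)


def reverse_search(
    contig: NucRecord,
    proteins: Sequence[ProtRecord],
    params: ScoringParams = DEFAULT_PARAMS,
    evalue_cutoff: float = DEFAULT_EVALUE,
) -> list[Hsp]:
    """Search a contig's six frames against a protein database (blastx roles).

    Query coordinates are contig nucleotides (qstart > qend on the minus
    strand), subject coordinates protein positions; the best hit per
    (protein, strand, frame) is reported with the same ordering as
    :func:`search`.
    """
    if not proteins:
        raise ValueError("empty protein database")
    frames = six_frame_translate(contig)
    db_size = sum(len(p.seq) for p in proteins)
    qlen = len(contig.seq)
    aligner = _make_aligner(params, "local")
    hsps: list[Hsp] = []
    for ft in frames:
        for prot in proteins:
            raw = aligner.score(ft.prot, prot.seq)
            if raw <= 0:
                continue
            bits = bitscore(raw, params)
            ev = evalue(bits, qlen, db_size)
            if ev > evalue_cutoff:
                continue
            raw_i, qa, sa, q0, q1, s0, s1 = local_align(ft.prot, prot.seq, params)
            matches, mismatches, gap_opens, align_len = _alignment_stats(qa, sa)
            n0, n1 = ft.nuc_interval(q0, q1)
            if ft.strand == "+":
                qstart, qend = n0 + 1, n1
            else:
                qstart, qend = n1, n0 + 1
            hsps.append(
                Hsp(
                    query_id=contig.id,
                    subject_id=prot.id,
                    pct_identity=round(100.0 * matches / align_len, 2),
                    align_len=align_len,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    qstart=qstart,
                    qend=qend,
                    sstart=s0 + 1,
                    send=s1,
                    evalue=ev,
                    bitscore=round(bits, 2),
                    raw_score=raw_i,
                    strand=ft.strand,
                    frame_offset=ft.offset,
                )
            )
    return _sort_hsps(hsps)


# ---------------------------------------------------------------------------
# Tabular (12-column outfmt-6 dialect) interchange
# ---------------------------------------------------------------------------

def format_tabular(hsp: Hsp) -> str:
    """One outfmt-6 line: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore."""
    return "\t".join(
        (
            hsp.query_id,
            hsp.subject_id,
            f"{hsp.pct_identity:.2f}",
            str(hsp.align_len),
            str(hsp.mismatches),
            str(hsp.gap_opens),
            str(hsp.qstart),
            str(hsp.qend),
            str(hsp.sstart),
            str(hsp.send),
            f"{hsp.evalue:.3g}",
            f"{hsp.bitscore:.1f}",
        )
    )


def write_tabular(hsps: Iterable[Hsp], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for hsp in hsps:
            fh.write(format_tabular(hsp) + "\n")
    return path


def read_tabular(path: str | Path) -> list[Hsp]:
    """Read a 12+ column tabular alignment file; extra columns are ignored.

    Strand is inferred from the subject coordinate order; the frame offset
    is not recoverable from the format and is reported as 0.
    """
    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns")
            sstart, send = int(cols[8]), int(cols[9])
            hsps.append(
                Hsp(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    align_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=sstart,
                    send=send,
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    strand="+" if sstart <= send else "-",
                )
            )
    return hsps
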