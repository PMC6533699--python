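"""Open reading frame detection on assembly contigs.

All six reading frames are scanned. A complete ORF runs ATG through the
next in-frame stop. Because contigs from short-read assemblies need not
span whole transcripts, partial ORFs are reported too and flagged:
5'-partial (no ATG before the frame's first stop; runs from the frame
start), 3'-partial (ATG with no downstream stop; runs to the frame end),
and both-ends-partial (a frame with neither ATG nor stop — a fragment
internal to a coding sequence). The longest ORF per contig serves as the
contig's protein representation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import NucRecord, reverse_complement, translate

DEFAULT_MIN_AA = 100


@dataclass(frozen=True)
class Orf:
    """An open reading frame located on a contig.

    ``start``/``end`` delimit the ORF (stop codon included when present) as
    a 0-based half-open interval on the forward strand; ``nuc_seq`` is the
    coding-orientation nucleotide sequence and ``protein`` its translation
    without the stop.
    """

    contig_id: str
    strand: str
    frame_offset: int
    start: int
    end: int
    nuc_seq: str
    protein: str
    partial5: bool = False
    partial3: bool = False

    @property
    def complete(self) -> bool:
        return not (self.partial5 or self.partial3)

    @property
    def partial(self) -> bool:
        return self.partial5 or self.partial3


def _orf_sort_key(orf: Orf):
    # Longest protein first; ties: complete before partial, + before -,
    # then smaller forward-strand start.
    return (-len(orf.protein), 0 if orf.complete else 1,
            0 if orf.strand == "+" else 1, orf.start)


def find_orfs(contig: NucRecord, min_aa: int = DEFAULT_MIN_AA) -> list[Orf]:
    """All ORFs of at least ``min_aa`` residues, longest protein first."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(contig.seq)
    if L < 3:
        return []
    orfs: list[Orf] = []
    rc = reverse_complement(contig.seq)
    for strand, seq in (("+", contig.seq), ("-", rc)):
        for offset in range(3):
            if L - offset < 3:
                continue
            prot = translate(seq, offset)
            orfs.extend(_scan_frame(contig.id, strand, offset, prot, L, seq, min_aa))
    return sorted(orfs, key=_orf_sort_key)


def _scan_frame(
    contig_id: str, strand: str, offset: int, prot: str, contig_len: int,
    working_seq: str, min_aa: int,
) -> Iterable[Orf]:
    """Scan one frame translation for ORFs.

    ``prot`` indexes codons of ``working_seq`` (the strand-oriented
    sequence) starting at ``offset``.
    """
    n = len(prot)
    seg_start = 0
    pos = 0
    while seg_start <= n:
        stop = prot.find("*", seg_start)
        seg_end = stop if stop != -1 else n  # segment is [seg_start, seg_end)
        has_stop = stop != -1
        first_m = prot.find("M", seg_start, seg_end)
        orf = None
        if first_m != -1:
            # complete (ATG..stop) or 3'-partial (ATG..frame end)
            p0, p1 = first_m, seg_end
            orf = _build(contig_id, strand, offset, p0, p1, has_stop,
                         partial5=False, partial3=not has_stop,
                         working_seq=working_seq, contig_len=contig_len)
        elif seg_start == 0:
            # no ATG before the first stop: 5'-partial from the frame start;
            # with no stop either, the fragment is partial at both ends
            p0, p1 = 0, seg_end
            if p1 > p0:
                orf = _build(contig_id, strand, offset, p0, p1, has_stop,
                             partial5=True, partial3=not has_stop,
                             working_seq=working_seq, contig_len=contig_len)
        if orf is not None and len(orf.protein) >= min_aa:
            yield orf
        if not has_stop:
            break
        seg_start = stop + 1


def _build(
    contig_id: str, strand: str, offset: int, p0: int, p1: int, include_stop: bool,
    partial5: bool, partial3: bool, working_seq: str, contig_len: int,
) -> Orf:
    w0 = offset + 3 * p0
    w1 = offset + 3 * (p1 + 1) if include_stop else offset + 3 * p1
    nuc = working_seq[w0:w1]
    if strand == "+":
        start, end = w0, w1
    else:
        start, end = contig_len - w1, contig_len - w0
    return Orf(
        contig_id=contig_id, strand=strand, frame_offset=offset,
        start=start, end=end, nuc_seq=nuc,
        protein=translate(nuc, 0).rstrip("*") if len(nuc) >= 3 else "",
        partial5=partial5, partial3=partial3,
    )


def longest_orf(
    contig: NucRecord, min_aa: int = DEFAULT_MIN_AA, allow_partial: bool = True
) -> Orf | None:
    """The contig's longest ORF, or None when nothing passes ``min_aa``.

    Ties are broken complete-before-partial, then + strand before -, then
    smaller forward-strand start. ``allow_partial=False`` restricts the
    choice to complete ORFs.
    """
    candidates = find_orfs(contig, min_aa)
    if not allow_partial:
        candidates = [o for o in candidates if o.complete]
    return candidates[0] if candidates else None


def write_bed(orfs: Sequence[Orf], path: str | Path) -> Path:
    """ORF coordinates as 6-column BED (0-based half-open, strand column)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, o in enumerate(orfs):
            name = f"{o.contig_id}.orf{i + 1}"
            fh.write(
                f"{o.contig_id}\t{o.start}\t{o.end}\t{name}\t{len(o.protein)}\t{o.strand}\n"
            )
    return path
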