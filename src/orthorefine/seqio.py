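"""Sequence data model and FASTA input/output.

Records are validated on construction: nucleotide sequences are normalised
to the {A, C, G, T, N} alphabet (U becomes T, other IUPAC ambiguity codes
become N with a logged warning), protein sequences to the 20 standard amino
acids plus X (unknown) and ``*`` (stop, trailing only).

Coordinate convention used throughout the package: 0-based half-open
intervals internally; 1-based inclusive coordinates only at serialisation
boundaries (the tabular alignment format).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id as _codon_tables

logger = logging.getLogger("orthorefine")

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

# IUPAC one-letter ambiguity codes collapsed to N on ingest.
_IUPAC_AMBIG = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1), stops rendered '*'.
_TABLE1 = dict(_codon_tables[1].forward_table)
_TABLE1.update({c: "*" for c in _codon_tables[1].stop_codons})


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA files."""


def _normalise_nuc(seq: str, record_id: str = "?") -> str:
    s = seq.upper().replace("U", "T")
    if set(s) <= NUC_ALPHABET:
        return s
    out = []
    for i, ch in enumerate(s):
        if ch in NUC_ALPHABET:
            out.append(ch)
        elif ch in _IUPAC_AMBIG:
            logger.warning(
                "record %s: IUPAC ambiguity code %r at position %d mapped to N",
                record_id, ch, i,
            )
            out.append("N")
        else:
            raise SequenceError(
                f"record {record_id}: invalid nucleotide {ch!r} at position {i}"
            )
    return "".join(out)


@dataclass(frozen=True)
class NucRecord:
    """A named nucleotide sequence (contig / cDNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id {self.id!r}")
        object.__setattr__(self, "seq", _normalise_nuc(self.seq, self.id))
        if not self.seq:
            raise SequenceError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProtRecord:
    """A named amino-acid sequence (bait / reference / predicted protein)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid record id {self.id!r}")
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        if not s:
            raise SequenceError(f"record {self.id}: empty sequence")
        for i, ch in enumerate(s):
            if ch not in PROT_ALPHABET:
                raise SequenceError(
                    f"record {self.id}: invalid amino acid {ch!r} at position {i}"
                )
        if "*" in s[:-1]:
            raise SequenceError(
                f"record {self.id}: internal stop codon ('*' before final position)"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, alphabet: str) -> list[NucRecord] | list[ProtRecord]:
    """Read a FASTA file into validated records.

    Parameters
    ----------
    path:
        FASTA file, wrapped or unwrapped, any case.
    alphabet:
        ``"nucleotide"`` or ``"protein"``.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = NucRecord if alphabet == "nucleotide" else ProtRecord
    path = Path(path)
    records: list = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(cls(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Sequence[NucRecord | ProtRecord], path: str | Path, wrap: int = 60
) -> Path:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` characters."""
    if not records:
        raise SequenceError("refusing to write empty record set")
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")
    return path


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    s = seq.upper()
    if not set(s) <= NUC_ALPHABET:
        bad = next(c for c in s if c not in NUC_ALPHABET)
        raise SequenceError(f"invalid nucleotide {bad!r} in reverse_complement input")
    return s.translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Stops are rendered ``*``. A codon containing N translates to the amino
    acid shared by all four substitutions, or X when they disagree. The
    trailing partial codon, if any, is dropped.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    s = seq.upper().replace("U", "T")
    if len(s) - offset < 3:
        raise SequenceError(
            f"sequence of length {len(s)} too short to translate at offset {offset}"
        )
    out = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        aa = _TABLE1.get(codon)
        if aa is None:
            aa = _translate_ambiguous(codon, i)
        out.append(aa)
    return "".join(out)


def _translate_ambiguous(codon: str, pos: int) -> str:
    for ch in codon:
        if ch not in NUC_ALPHABET:
            raise SequenceError(f"invalid nucleotide {ch!r} at position {pos}")
    variants = [""]
    for ch in codon:
        bases = "ACGT" if ch == "N" else ch
        variants = [v + b for v in variants for b in bases]
    aas = {_TABLE1[v] for v in variants}
    return aas.pop() if len(aas) == 1 else "X"
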