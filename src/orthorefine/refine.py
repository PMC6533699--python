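"""Refinement quantification and multiple alignment for visual inspection.

Directional pairwise identities follow the Ensembl orthology convention:
after a global (end-gap penalised, affine) alignment of sequences a and b,
identity with respect to a is 100 * matches / len(a) and likewise for b —
the denominator is the full ungapped sequence length, not the alignment
length. The difference of the two directional identities signals length
discrepancies: a truncated orthologue matches its bait over its whole
(short) length while the bait is only partially matched.

Refinement of an annotated target is quantified as the decrease in the
absolute identity difference (old target vs bait, refined target vs bait).
When no prior annotation exists, the fallback compares the fractions of
the refined sequence and of the bait covered by their best local alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .seqio import ProtRecord
from .translate_search import (
    DEFAULT_PARAMS,
    ScoringParams,
    _alignment_stats,
    _make_aligner,
    local_align,
)


@dataclass(frozen=True)
class PairwiseIdentity:
    """Directional identities of a global alignment of sequences a and b."""

    matches: int
    aln_cols: int
    id_wrt_a: float  # 100 * matches / len(a)
    id_wrt_b: float  # 100 * matches / len(b)

    @property
    def signed_difference(self) -> float:
        return self.id_wrt_a - self.id_wrt_b

    @property
    def abs_difference(self) -> float:
        return abs(self.signed_difference)


def query_coverage(qstart: int, qend: int, qlen: int) -> float:
    """Percent of a query of length ``qlen`` covered by an alignment spanning
    1-based inclusive positions ``qstart``..``qend``."""
    if not (1 <= qstart <= qend <= qlen):
        raise ValueError(
            f"require 1 <= qstart <= qend <= qlen, got ({qstart}, {qend}, {qlen})"
        )
    return 100.0 * (qend - qstart + 1) / qlen


_MATCH_TIEBREAK_SCALE = 65536


def _tiebreak_aligner(params: ScoringParams):
    """Global aligner whose scores are scale*score + matches.

    Scaling the matrix and gap penalties by a factor far larger than any
    possible match count and adding +1 on the diagonal makes the optimal
    alignments exactly those that first maximise the alignment score and
    then, among co-optimal ones, the number of identical pairs — so the
    identity statistic is well defined.
    """
    from Bio.Align import PairwiseAligner, substitution_matrices

    base = substitution_matrices.load(params.matrix)
    scaled = base * _MATCH_TIEBREAK_SCALE
    for ch in base.alphabet:
        scaled[ch, ch] += 1
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scaled
    aligner.open_gap_score = -_MATCH_TIEBREAK_SCALE * (params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -_MATCH_TIEBREAK_SCALE * params.gap_extend
    return aligner


def pairwise_identity(
    a: str, b: str, params: ScoringParams = DEFAULT_PARAMS
) -> PairwiseIdentity:
    """Global-alignment identity of two protein strings, both directions.

    Among co-optimal global alignments the one with the most identical
    aligned pairs is used.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _tiebreak_aligner(params)
    aln = aligner.align(a, b)[0]
    qa, sa = aln[0], aln[1]
    matches, _, _, aln_cols = _alignment_stats(qa, sa)
    return PairwiseIdentity(
        matches=matches,
        aln_cols=aln_cols,
        id_wrt_a=100.0 * matches / len(a),
        id_wrt_b=100.0 * matches / len(b),
    )


@dataclass
class RefinementReport:
    """Before/after comparison of a target sequence against its bait.

    In identity mode the ``*_diff`` fields are identity differences (target
    vs bait); in coverage mode (no prior annotation) they are alignment
    coverages of the refined sequence and of the bait. ``delta`` is the
    decrease in absolute identity difference achieved by the refinement
    (identity mode) or the signed coverage difference (coverage mode).
    """

    bait_id: str
    refined_id: str
    mode: str  # 'identity' or 'coverage'
    old_target_id: str | None = None
    # identity mode
    old_id_wrt_target: float | None = None
    old_id_wrt_bait: float | None = None
    old_diff_signed: float | None = None
    old_diff_abs: float | None = None
    refined_id_wrt_target: float | None = None
    refined_id_wrt_bait: float | None = None
    refined_diff_signed: float | None = None
    refined_diff_abs: float | None = None
    # coverage mode
    coverage_wrt_refined: float | None = None
    coverage_wrt_bait: float | None = None
    delta: float = 0.0
    msa_path: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def refinement_delta(
    bait: ProtRecord,
    refined: ProtRecord,
    old_target: ProtRecord | None = None,
    params: ScoringParams = DEFAULT_PARAMS,
) -> RefinementReport:
    """Quantify a refinement of ``old_target`` into ``refined`` against ``bait``.

    With an annotated target, reports the absolute identity difference of
    the old and the refined sequence against the bait and their decrease.
    Without one, reports how much of the refined sequence and of the bait
    the best local alignment covers, and the signed difference.
    """
    if old_target is not None:
        pi_old = pairwise_identity(old_target.seq, bait.seq, params)
        pi_new = pairwise_identity(refined.seq, bait.seq, params)
        return RefinementReport(
            bait_id=bait.id,
            refined_id=refined.id,
            mode="identity",
            old_target_id=old_target.id,
            old_id_wrt_target=pi_old.id_wrt_a,
            old_id_wrt_bait=pi_old.id_wrt_b,
            old_diff_signed=pi_old.signed_difference,
            old_diff_abs=pi_old.abs_difference,
            refined_id_wrt_target=pi_new.id_wrt_a,
            refined_id_wrt_bait=pi_new.id_wrt_b,
            refined_diff_signed=pi_new.signed_difference,
            refined_diff_abs=pi_new.abs_difference,
            delta=pi_old.abs_difference - pi_new.abs_difference,
        )
    raw, qa, sa, q0, q1, s0, s1 = local_align(refined.seq, bait.seq, params)
    if raw == 0:
        cov_r = cov_b = 0.0
    else:
        cov_r = query_coverage(q0 + 1, q1, len(refined.seq))
        cov_b = query_coverage(s0 + 1, s1, len(bait.seq))
    return RefinementReport(
        bait_id=bait.id,
        refined_id=refined.id,
        mode="coverage",
        coverage_wrt_refined=cov_r,
        coverage_wrt_bait=cov_b,
        delta=cov_r - cov_b,
    )


def write_reports_tsv(reports: Sequence[RefinementReport], path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(path, sep="\t", index=False)
    return path


def write_reports_json(reports: Sequence[RefinementReport], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def center_star_msa(
    records: Sequence[ProtRecord], params: ScoringParams = DEFAULT_PARAMS
) -> list[tuple[str, str]]:
    """Progressive multiple alignment around a center sequence.

    The center is the input with maximal summed pairwise global-alignment
    score to the others (ties: first in input order); every other sequence
    is merged through its pairwise alignment with the center under the
    once-a-gap-always-a-gap rule. Returns ``(id, aligned_seq)`` pairs in the
    input order; ungapping any row recovers its input sequence.
    """
    if len(records) < 2:
        raise ValueError("multiple alignment needs at least 2 sequences")
    aligner = _make_aligner(params, "global")
    n = len(records)
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(records[i].seq, records[j].seq)
            scores[i][j] = scores[j][i] = s
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))

    center_seq = records[center].seq
    master = list(center_seq)  # center row with accumulated gaps
    rows: dict[int, list[str]] = {center: master}
    for j in range(n):
        if j == center:
            continue
        aln = aligner.align(center_seq, records[j].seq)[0]
        ca, ja = aln[0], aln[1]
        _merge(rows, master, ca, ja, j)
    out = []
    for idx, rec in enumerate(records):
        out.append((rec.id, "".join(rows[idx])))
    return out


def _merge(rows: dict[int, list[str]], master: list[str], ca: str, ja: str, j: int) -> None:
    """Thread a new pairwise alignment (center row ca, new row ja) into the
    master alignment, inserting gap columns where the two disagree."""
    new_row: list[str] = []
    mi = 0  # index into master
    pi = 0  # index into ca/ja
    while mi < len(master) or pi < len(ca):
        m_gap = mi < len(master) and master[mi] == "-"
        p_gap = pi < len(ca) and ca[pi] == "-"
        if mi < len(master) and pi < len(ca) and m_gap == p_gap:
            # same center residue, or j's insertion reuses an existing gap column
            new_row.append(ja[pi])
            mi += 1
            pi += 1
        elif p_gap:
            # pairwise alignment inserts a gap into the center: open a new
            # column in the master and all existing rows
            master.insert(mi, "-")
            for idx, row in rows.items():
                if row is not master:
                    row.insert(mi, "-")
            new_row.append(ja[pi])
            mi += 1
            pi += 1
        else:
            # master has a gap the pairwise alignment lacks
            new_row.append("-")
            mi += 1
    rows[j] = new_row


def write_msa_fasta(msa: Sequence[tuple[str, str]], path: str | Path, wrap: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in msa:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
    return path
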