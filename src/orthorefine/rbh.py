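"""Reciprocal best-hit validation of bait proteins against an assembly.

A bait protein is searched against the contig database (translated,
six-frame); the n best contigs by (bitscore, e-value) are carried to a
reverse search against the reference protein set. The bait counts as a
reciprocal best hit (RBH) when the top-ranked contig's best reverse hit is
the bait itself — the standard operational criterion for having recovered
the right coding sequence. The reverse query is either the whole contig
(blastx-style validation) or the contig's longest ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .orf import DEFAULT_MIN_AA, longest_orf
from .seqio import NucRecord, ProtRecord
from .translate_search import (
    DEFAULT_EVALUE,
    DEFAULT_PARAMS,
    Hsp,
    ScoringParams,
    _make_aligner,
    _sort_hsps,
    bitscore,
    evalue,
    local_align,
    reverse_search,
    search,
    six_frame_translate,
    _alignment_stats,
)

REVERSE_MODES = ("whole_contig", "longest_orf")


@dataclass
class RbhResult:
    """Outcome of the reciprocal search for one bait protein."""

    bait_id: str
    best_contig_ids: list[str]
    forward_hsps: dict[str, Hsp]
    reverse_top_ids: dict[str, str | None]
    is_rbh: bool
    reverse_mode: str


def best_contigs(hsps: Sequence[Hsp], n: int = 1) -> list[str]:
    """The first ``n`` distinct subject (contig) ids under the
    (bitscore desc, evalue asc, id asc) ordering."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[str] = []
    for hsp in _sort_hsps(list(hsps)):
        if hsp.subject_id not in out:
            out.append(hsp.subject_id)
            if len(out) == n:
                break
    return out


def _protein_vs_proteins(
    query_prot: str,
    query_id: str,
    proteins: Sequence[ProtRecord],
    params: ScoringParams,
    evalue_cutoff: float,
) -> list[Hsp]:
    """Rank a protein query against a protein database (longest-ORF reverse
    mode); scoring and ordering as in the translated searches."""
    db_size = sum(len(p.seq) for p in proteins)
    qlen = len(query_prot)
    aligner = _make_aligner(params, "local")
    hsps: list[Hsp] = []
    for prot in proteins:
        raw = aligner.score(query_prot, prot.seq)
        if raw <= 0:
            continue
        bits = bitscore(raw, params)
        ev = evalue(bits, qlen, db_size)
        if ev > evalue_cutoff:
            continue
        raw_i, qa, sa, q0, q1, s0, s1 = local_align(query_prot, prot.seq, params)
        matches, mismatches, gap_opens, align_len = _alignment_stats(qa, sa)
        hsps.append(
            Hsp(
                query_id=query_id,
                subject_id=prot.id,
                pct_identity=round(100.0 * matches / align_len, 2),
                align_len=align_len,
                mismatches=mismatches,
                gap_opens=gap_opens,
                qstart=q0 + 1,
                qend=q1,
                sstart=s0 + 1,
                send=s1,
                evalue=ev,
                bitscore=round(bits, 2),
                raw_score=raw_i,
            )
        )
    return _sort_hsps(hsps)


def _reverse_top(
    contig: NucRecord,
    reference_proteins: Sequence[ProtRecord],
    params: ScoringParams,
    evalue_cutoff: float,
    reverse_mode: str,
    min_aa: int,
) -> str | None:
    if reverse_mode == "whole_contig":
        hits = reverse_search(contig, reference_proteins, params, evalue_cutoff)
    else:
        orf = longest_orf(contig, min_aa)
        if orf is None:
            return None
        hits = _protein_vs_proteins(
            orf.protein, contig.id, reference_proteins, params, evalue_cutoff
        )
    return hits[0].subject_id if hits else None


def reciprocal_best_hit(
    bait: ProtRecord,
    contigs: Sequence[NucRecord],
    reference_proteins: Sequence[ProtRecord],
    params: ScoringParams = DEFAULT_PARAMS,
    n: int = 1,
    evalue_cutoff: float = DEFAULT_EVALUE,
    reverse_mode: str = "whole_contig",
    min_aa: int = DEFAULT_MIN_AA,
    frames=None,
) -> RbhResult:
    """Run the forward and reverse search for one bait protein.

    ``is_rbh`` is decided on the top-ranked contig only; the remaining
    n-1 contigs are reported but do not affect the flag.
    """
    if reverse_mode not in REVERSE_MODES:
        raise ValueError(f"reverse_mode must be one of {REVERSE_MODES}")
    ref_ids = {p.id for p in reference_proteins}
    if bait.id not in ref_ids:
        raise ValueError(
            f"bait {bait.id!r} missing from the reference protein set; "
            "the reciprocal check cannot validate it"
        )
    fwd = search(bait, contigs, params, evalue_cutoff, frames=frames)
    top_ids = best_contigs(fwd, n)
    by_id = {c.id: c for c in contigs}
    fwd_best: dict[str, Hsp] = {}
    for hsp in fwd:
        fwd_best.setdefault(hsp.subject_id, hsp)
    reverse_top_ids: dict[str, str | None] = {}
    for cid in top_ids:
        reverse_top_ids[cid] = _reverse_top(
            by_id[cid], reference_proteins, params, evalue_cutoff, reverse_mode, min_aa
        )
    is_rbh = bool(top_ids) and reverse_top_ids[top_ids[0]] == bait.id
    return RbhResult(
        bait_id=bait.id,
        best_contig_ids=top_ids,
        forward_hsps={cid: fwd_best[cid] for cid in top_ids},
        reverse_top_ids=reverse_top_ids,
        is_rbh=is_rbh,
        reverse_mode=reverse_mode,
    )


def run_rbh(
    baits: Sequence[ProtRecord],
    contigs: Sequence[NucRecord],
    reference_proteins: Sequence[ProtRecord],
    params: ScoringParams = DEFAULT_PARAMS,
    n: int = 1,
    evalue_cutoff: float = DEFAULT_EVALUE,
    reverse_mode: str = "whole_contig",
    min_aa: int = DEFAULT_MIN_AA,
) -> list[RbhResult]:
    """Reciprocal search for a batch of baits against one contig database.

    Six-frame translations of the database are computed once and shared
    across baits. An empty contig database yields all-negative results.
    """
    if not contigs:
        return [
            RbhResult(b.id, [], {}, {}, False, reverse_mode) for b in baits
        ]
    frames = [f for c in contigs for f in six_frame_translate(c)]
    return [
        reciprocal_best_hit(
            b, contigs, reference_proteins, params, n, evalue_cutoff,
            reverse_mode, min_aa, frames=frames,
        )
        for b in baits
    ]


def detection_rate(results: Sequence[RbhResult], total_baits: int) -> float:
    """Percent of baits recovered as reciprocal best hits."""
    if total_baits == 0:
        raise ValueError("total_baits must be positive")
    hits = sum(1 for r in results if r.is_rbh)
    if total_baits < hits:
        raise ValueError("total_baits smaller than the number of RBH results")
    return 100.0 * hits / total_baits


def rbh_set_summary(sets: Mapping[str, Iterable]) -> dict:
    """Exclusive intersection-region counts for named RBH id sets.

    For every non-empty subset of set names the count of ids belonging to
    exactly those sets is reported (UpSet semantics), together with
    per-set totals and the union size. The region counts partition the
    union.
    """
    named = {name: set(s) for name, s in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 named sets")
    names = sorted(named)
    union = set().union(*named.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named[c] for c in combo))
            outside = set().union(
                *(named[o] for o in names if o not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return {
        "regions": regions,
        "totals": {name: len(named[name]) for name in names},
        "union": len(union),
    }


def write_rbh_tsv(
    results: Sequence[RbhResult],
    path: str | Path,
    bait_lengths: Mapping[str, int] | None = None,
) -> Path:
    """Per-bait report: id, RBH flag, best contig, forward hit statistics,
    reverse top hit. Coverage (percent of the bait spanned by the forward
    alignment) is emitted when ``bait_lengths`` is given."""
    from .refine import query_coverage

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "bait_id\tis_rbh\tbest_contig\tfwd_bitscore\tfwd_evalue\t"
            "fwd_coverage\tfwd_identity\treverse_top_id\n"
        )
        for r in results:
            if r.best_contig_ids:
                top = r.best_contig_ids[0]
                hsp = r.forward_hsps[top]
                if bait_lengths and r.bait_id in bait_lengths:
                    cov = f"{query_coverage(hsp.qstart, hsp.qend, bait_lengths[r.bait_id]):.2f}"
                else:
                    cov = f"{hsp.qstart}-{hsp.qend}"
                fh.write(
                    f"{r.bait_id}\t{r.is_rbh}\t{top}\t{hsp.bitscore}\t"
                    f"{hsp.evalue:.3g}\t{cov}\t"
                    f"{hsp.pct_identity}\t{r.reverse_top_ids.get(top) or ''}\n"
                )
            else:
                fh.write(f"{r.bait_id}\t{r.is_rbh}\t\t\t\t\t\t\n")
    return path


def write_set_summary_tsv(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for combo, count in sorted(summary["regions"].items()):
            fh.write("&".join(combo) + f"\t{count}\n")
        for name, total in summary["totals"].items():
            fh.write(f"total:{name}\t{total}\n")
        fh.write(f"union\t{summary['union']}\n")
    return path
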