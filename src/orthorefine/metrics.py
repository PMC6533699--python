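"""Assembly summary metrics for a contig set.

Reports contig counts and lengths together with the two coding-potential
indicators used to characterise transcriptome assemblies: how many contigs
contain an open reading frame of at least ``min_aa`` residues, and — over
those contigs — the mean percentage of the contig covered by its longest
ORF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from .orf import DEFAULT_MIN_AA, longest_orf
from .seqio import NucRecord


@dataclass(frozen=True)
class AssemblyMetrics:
    n_contigs: int
    max_len: int
    mean_len: float
    n_with_orf: int
    mean_orf_coverage: float | None  # None when no contig carries an ORF

    def to_dict(self) -> dict:
        return asdict(self)


def assembly_metrics(
    contigs: Sequence[NucRecord], min_aa: int = DEFAULT_MIN_AA
) -> AssemblyMetrics:
    """Summary statistics of a contig FASTA.

    ORF presence and coverage use each contig's longest ORF (partial ORFs
    eligible), consistent with the pipeline's protein-representation
    choice.
    """
    if not contigs:
        raise ValueError("empty contig set")
    lengths = [len(c.seq) for c in contigs]
    coverages = []
    for contig in contigs:
        orf = longest_orf(contig, min_aa)
        if orf is not None:
            coverages.append(100.0 * len(orf.nuc_seq) / len(contig.seq))
    return AssemblyMetrics(
        n_contigs=len(contigs),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        n_with_orf=len(coverages),
        mean_orf_coverage=(sum(coverages) / len(coverages)) if coverages else None,
    )


def write_metrics(metrics: AssemblyMetrics, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2)
            fh.write("\n")
    else:
        d = metrics.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join("" if v is None else str(v) for v in d.values()) + "\n")
    return path
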