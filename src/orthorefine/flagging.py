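"""Flagging of presumably poorly annotated orthologues.

Input is a per-gene orthology identity table (one row per gene x species)
carrying the two directional identities of the Ensembl orthology
convention: target identity (percent of the orthologous sequence matching
the reference protein) and query identity (percent of the reference
protein matching the orthologue). Their difference signals length
discrepancies — e.g. target 98 / query 80 points at a truncated
orthologue. Per species, genes whose absolute identity difference exceeds
the species mean + 2 standard deviations are flagged; a cross-species
filter keeps only genes flagged in exactly one species (conserved
elsewhere), separating annotation problems from genuine divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

COLUMNS = ("gene_id", "species", "target_identity", "query_identity")


@dataclass(frozen=True)
class OrthologyRecord:
    """Directional identities of one gene's orthologue in one species."""

    gene_id: str
    species: str
    target_identity: float
    query_identity: float

    def __post_init__(self) -> None:
        for name in ("target_identity", "query_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")


@dataclass
class FlagTable:
    """Per-species flagging outcome plus the cross-species uniqueness filter."""

    thresholds: dict[str, float]
    flagged: dict[str, set[str]]
    cross_species: set[str] = field(default_factory=set)


def identity_difference(rec: OrthologyRecord) -> float:
    """Signed identity difference, target minus query."""
    return rec.target_identity - rec.query_identity


def species_threshold(
    diffs: Sequence[float], use_absolute: bool = True, ddof: int = 1
) -> float:
    """Outlier threshold mean + 2*SD of the (absolute) identity differences.

    Sample standard deviation (n-1 denominator) by default.
    """
    if len(diffs) < 2:
        raise ValueError("need at least 2 identity differences")
    x = np.abs(np.asarray(diffs, dtype=float)) if use_absolute else np.asarray(diffs, dtype=float)
    return float(x.mean() + 2.0 * x.std(ddof=ddof))


def flag_genes(
    records: Sequence[OrthologyRecord] | pd.DataFrame,
    use_absolute: bool = True,
    ddof: int = 1,
) -> FlagTable:
    """Flag genes whose absolute identity difference exceeds the species
    threshold, and apply the cross-species uniqueness filter.

    The cross-species set contains genes with records in every species that
    are flagged in exactly one of them. One record per gene x species is
    required.
    """
    df = _as_frame(records)
    dup = df.duplicated(subset=["gene_id", "species"])
    if dup.any():
        g, s = df.loc[dup, ["gene_id", "species"]].iloc[0]
        raise ValueError(f"duplicated gene x species entry: {g} / {s}")
    df = df.assign(diff=df["target_identity"] - df["query_identity"])
    thresholds: dict[str, float] = {}
    flagged: dict[str, set[str]] = {}
    for species, sub in df.groupby("species"):
        thr = species_threshold(sub["diff"].tolist(), use_absolute, ddof)
        thresholds[species] = thr
        flagged[species] = set(sub.loc[sub["diff"].abs() > thr, "gene_id"])
    n_species = df["species"].nunique()
    cross: set[str] = set()
    if n_species >= 2:
        counts = df.groupby("gene_id")["species"].nunique()
        complete = set(counts[counts == n_species].index)
        for gene in complete:
            hits = sum(1 for s in flagged if gene in flagged[s])
            if hits == 1:
                cross.add(gene)
    return FlagTable(thresholds=thresholds, flagged=flagged, cross_species=cross)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return records.loc[:, list(COLUMNS)].copy()
    return pd.DataFrame(
        [
            (r.gene_id, r.species, r.target_identity, r.query_identity)
            for r in records
        ],
        columns=list(COLUMNS),
    )


def read_identity_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV identity table (gene_id, species, target_identity,
    query_identity) — the shape of an Ensembl orthology export."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_flag_tables(table: FlagTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write per-species flags and the cross-species gene list as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_species = out_dir / "flags_per_species.tsv"
    with open(per_species, "w") as fh:
        fh.write("species\tthreshold\tgene_id\n")
        for species in sorted(table.flagged):
            thr = table.thresholds[species]
            for gene in sorted(table.flagged[species]):
                fh.write(f"{species}\t{thr:.6f}\t{gene}\n")
    cross = out_dir / "flags_cross_species.tsv"
    with open(cross, "w") as fh:
        fh.write("gene_id\n")
        for gene in sorted(table.cross_species):
            fh.write(gene + "\n")
    return per_species, cross
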