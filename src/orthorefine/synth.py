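"""Synthetic ortholog families with known ground truth.

The generator emulates the study design of the refinement workflow:
ancestral coding sequences stand in for the well-annotated reference
(bait) proteome; species orthologues diverge from them by codon-level
point substitution to a controlled protein identity; expressed genes shed
contigs — substrings of their CDS, optionally one guaranteed full-length,
with random strand — standing in for a de novo assembly; and a configurable
fraction of the species' annotated proteins is truncated at the N- or
C-terminus, emulating incomplete database annotations. Optional paralog
genes (always expressed) let tests probe reciprocal-best-hit confusion.

Divergence is substitution-only (no indels) and never touches the start
codon or creates internal stops, so planted CDSs remain complete ORFs and
the realised protein identity is controlled exactly: d = round((1-t)*L)
positions are substituted for a target identity t, giving (L-d)/L.
All randomness flows from the config seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import NucRecord, ProtRecord, reverse_complement, translate, write_fasta
from .seqio import _TABLE1 as _CODE

_SENSE_CODONS = sorted(c for c, aa in _CODE.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in _CODE.items() if aa == "*")
_BY_AA: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    _BY_AA.setdefault(_CODE[_c], []).append(_c)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ortholog family.

    ``species_identity`` maps each simulated species to the target protein
    identity of its orthologues against the reference. Fragment lengths
    are drawn from a normal distribution (mean/sd, floored at
    ``fragment_min``); ``full_length`` additionally guarantees one complete
    CDS contig per expressed gene.
    """

    n_genes: int = 50
    protein_len_range: tuple[int, int] = (300, 600)
    species_identity: Mapping[str, float] = field(
        default_factory=lambda: {"target_species": 0.9}
    )
    p_expressed: float = 0.7
    fragment_mean: float = 800.0
    fragment_sd: float = 200.0
    fragment_min: int = 300
    n_fragments: int = 2
    full_length: bool = True
    truncated_fraction: float = 0.2
    truncation_range: tuple[float, float] = (0.1, 0.4)
    truncation_end: str = "N"
    paralog_count: int = 0
    paralog_identity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_expressed <= 1.0:
            raise ValueError("p_expressed must be in [0, 1]")
        if not 0.0 <= self.truncated_fraction <= 1.0:
            raise ValueError("truncated_fraction must be in [0, 1]")
        for sp, t in self.species_identity.items():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"identity target for {sp} outside (0, 1]: {t}")
        if self.truncation_end not in ("N", "C"):
            raise ValueError("truncation_end must be 'N' or 'C'")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["species_identity"] = dict(self.species_identity)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("protein_len_range", "truncation_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GeneTruth:
    gene_id: str
    paralog_of: str | None = None
    true_protein: dict = field(default_factory=dict)   # species -> protein
    annotated: dict = field(default_factory=dict)      # species -> protein
    expressed: dict = field(default_factory=dict)      # species -> bool
    truncated: dict = field(default_factory=dict)      # species -> bool
    contig_ids: dict = field(default_factory=dict)     # species -> [ids]


@dataclass
class SimTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneTruth:
        if gene_id not in self.genes:
            self.genes[gene_id] = GeneTruth(gene_id=gene_id)
        return self.genes[gene_id]


@dataclass
class FamilySim:
    """Everything simulate_family produced, plus room for contigs."""

    config: SimConfig
    reference_proteins: list[ProtRecord]
    reference_cds: list[NucRecord]
    species_proteins: dict[str, list[ProtRecord]]
    species_cds: dict[str, list[NucRecord]]
    annotated_proteins: dict[str, list[ProtRecord]]
    truth: SimTruth
    contigs: dict[str, list[NucRecord]] = field(default_factory=dict)


def _random_cds(length_aa: int, rng: np.random.Generator) -> str:
    """A CDS of ``length_aa`` residues: ATG, random sense codons, one stop."""
    body = rng.choice(len(_SENSE_CODONS), size=length_aa - 1)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def mutate_cds(cds: str, identity: float, rng: np.random.Generator) -> str:
    """Derive an orthologous CDS at the given protein identity.

    Exactly ``round((1 - identity) * L)`` positions (never the start codon)
    receive a codon of a different, non-stop amino acid, so the realised
    identity is within half a residue of the target.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"unreachable identity target: {identity}")
    L = len(cds) // 3 - 1  # protein length excluding stop
    d = int(round((1.0 - identity) * L))
    if d == 0:
        return cds
    if d > L - 1:
        raise ValueError(f"cannot place {d} substitutions in {L - 1} mutable codons")
    positions = rng.choice(np.arange(1, L), size=d, replace=False)
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
    for p in positions:
        current = _CODE[codons[p]]
        choices = [c for c in _SENSE_CODONS if _CODE[c] != current]
        codons[p] = choices[rng.integers(len(choices))]
    return "".join(codons)


def truncate_annotation(protein: str, k: int, end: str = "N") -> str:
    """Remove ``k`` residues from the N- or C-terminus of a protein."""
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    if not 0 < k < len(protein):
        raise ValueError(f"k must be in (0, {len(protein)}), got {k}")
    return protein[k:] if end == "N" else protein[:-k]


def simulate_family(cfg: SimConfig, rng: np.random.Generator | None = None) -> FamilySim:
    """Generate the reference proteome, per-species orthologues, annotations
    and expression indicators with full ground-truth bookkeeping."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truth = SimTruth()
    lo, hi = cfg.protein_len_range
    ref_prot: list[ProtRecord] = []
    ref_cds: list[NucRecord] = []
    gene_ids: list[tuple[str, str | None]] = []  # (gene_id, paralog_of)
    ancestors: dict[str, str] = {}
    for g in range(cfg.n_genes):
        gid = f"g{g + 1:04d}"
        cds = _random_cds(int(rng.integers(lo, hi + 1)), rng)
        ancestors[gid] = cds
        gene_ids.append((gid, None))
        for p in range(cfg.paralog_count):
            pid = f"{gid}_p{p + 1}"
            ancestors[pid] = mutate_cds(cds, cfg.paralog_identity, rng)
            gene_ids.append((pid, gid))
    for gid, parent in gene_ids:
        cds = ancestors[gid]
        ref_cds.append(NucRecord(id=gid, seq=cds))
        ref_prot.append(ProtRecord(id=gid, seq=translate(cds, 0).rstrip("*")))
        truth.gene(gid).paralog_of = parent

    species_prot: dict[str, list[ProtRecord]] = {}
    species_cds: dict[str, list[NucRecord]] = {}
    annotated: dict[str, list[ProtRecord]] = {}
    for sp, ident in cfg.species_identity.items():
        prots, cdss, annots = [], [], []
        main_genes = [gid for gid, parent in gene_ids if parent is None]
        n_trunc = int(round(cfg.truncated_fraction * len(main_genes)))
        trunc_set = set(
            rng.choice(main_genes, size=n_trunc, replace=False)
        ) if n_trunc else set()
        for gid, parent in gene_ids:
            cds = mutate_cds(ancestors[gid], ident, rng)
            protein = translate(cds, 0).rstrip("*")
            gt = truth.gene(gid)
            gt.true_protein[sp] = protein
            cdss.append(NucRecord(id=gid, seq=cds))
            prots.append(ProtRecord(id=gid, seq=protein))
            # paralogs are always expressed; main genes with probability p
            expressed = True if parent else bool(rng.random() < cfg.p_expressed)
            gt.expressed[sp] = expressed
            if parent is None:
                if gid in trunc_set:
                    frac = rng.uniform(*cfg.truncation_range)
                    k = max(1, min(len(protein) - 1, int(round(frac * len(protein)))))
                    ann = truncate_annotation(protein, k, cfg.truncation_end)
                    gt.truncated[sp] = True
                else:
                    ann = protein
                    gt.truncated[sp] = False
                gt.annotated[sp] = ann
                annots.append(ProtRecord(id=gid, seq=ann))
        species_prot[sp] = prots
        species_cds[sp] = cdss
        annotated[sp] = annots
    return FamilySim(
        config=cfg,
        reference_proteins=ref_prot,
        reference_cds=ref_cds,
        species_proteins=species_prot,
        species_cds=species_cds,
        annotated_proteins=annotated,
        truth=truth,
    )


def fragment_transcripts(
    cds_records: Sequence[NucRecord],
    cfg: SimConfig,
    truth: SimTruth,
    species: str,
    rng: np.random.Generator | None = None,
) -> list[NucRecord]:
    """Fragment expressed genes' CDSs into contigs.

    Every expressed gene emits at least one contig (the full CDS when
    ``full_length`` is set) plus ``n_fragments`` random substrings with
    lengths drawn from the configured normal distribution; each contig is
    reverse-complemented with probability 0.5. Unexpressed genes emit
    nothing.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    contigs: list[NucRecord] = []
    for rec in cds_records:
        gt = truth.gene(rec.id)
        if not gt.expressed.get(species, False):
            gt.contig_ids.setdefault(species, [])
            continue
        ids: list[str] = []
        pieces: list[str] = []
        if cfg.full_length or cfg.n_fragments == 0:
            pieces.append(rec.seq)  # expressed genes emit >= 1 contig
        for _ in range(cfg.n_fragments):
            length = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
            length = max(cfg.fragment_min, min(length, len(rec.seq)))
            start = int(rng.integers(0, len(rec.seq) - length + 1))
            pieces.append(rec.seq[start : start + length])
        for i, piece in enumerate(pieces):
            cid = f"{rec.id}_c{i}"
            if rng.random() < 0.5:
                piece = reverse_complement(piece)
            contigs.append(NucRecord(id=cid, seq=piece))
            ids.append(cid)
        gt.contig_ids[species] = ids
    return contigs


def write_truth_tsv(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    species = sorted({sp for gt in truth.genes.values() for sp in gt.expressed})
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tparalog_of\tspecies\texpressed\ttruncated\t"
            "true_protein_len\tannotated_len\tcontig_ids\n"
        )
        for gid in sorted(truth.genes):
            gt = truth.genes[gid]
            for sp in species:
                if sp not in gt.true_protein:
                    continue
                fh.write(
                    f"{gid}\t{gt.paralog_of or ''}\t{sp}\t"
                    f"{gt.expressed.get(sp, False)}\t{gt.truncated.get(sp, '')}\t"
                    f"{len(gt.true_protein[sp])}\t"
                    f"{len(gt.annotated.get(sp, '')) or ''}\t"
                    f"{','.join(gt.contig_ids.get(sp, []))}\n"
                )
    return path


def run_simulation(cfg: SimConfig, out_dir: str | Path) -> FamilySim:
    """Simulate a family, fragment every species' transcripts, and write
    the fixture directory (FASTAs + truth TSV + config JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_family(cfg, rng)
    for sp in cfg.species_identity:
        sim.contigs[sp] = fragment_transcripts(
            sim.species_cds[sp], cfg, sim.truth, sp, rng
        )
    cfg.to_json(out_dir / "sim_config.json")
    write_fasta(sim.reference_proteins, out_dir / "reference_proteins.fasta")
    write_fasta(sim.reference_cds, out_dir / "reference_cds.fasta")
    for sp in cfg.species_identity:
        write_fasta(sim.species_proteins[sp], out_dir / f"{sp}_true_proteins.fasta")
        if sim.annotated_proteins[sp]:
            write_fasta(sim.annotated_proteins[sp], out_dir / f"{sp}_annotated.fasta")
        if sim.contigs[sp]:
            write_fasta(sim.contigs[sp], out_dir / f"{sp}_contigs.fasta")
    write_truth_tsv(sim.truth, out_dir / "truth.tsv")
    return sim
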