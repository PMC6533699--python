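"""Synthetic ortholog-family generator: determinism and ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from orthorefine.refine import pairwise_identity
from orthorefine.seqio import reverse_complement, translate
from orthorefine.synth import (
    SimConfig,
    fragment_transcripts,
    mutate_cds,
    run_simulation,
    simulate_family,
    truncate_annotation,
    _random_cds,
)


def small_cfg(**kw) -> SimConfig:
    defaults = dict(
        n_genes=8,
        protein_len_range=(80, 120),
        species_identity={"sp": 0.9},
        p_expressed=1.0,
        fragment_mean=150.0,
        fragment_sd=30.0,
        fragment_min=60,
        n_fragments=2,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMutateCds:
    def test_identity_one_is_identity(self, rng):
        cds = _random_cds(100, rng)
        assert mutate_cds(cds, 1.0, rng) == cds

    def test_realised_identity_matches_target(self, rng):
        for target in (0.95, 0.9, 0.7):
            cds = _random_cds(300, rng)
            mutated = mutate_cds(cds, target, rng)
            a = translate(cds, 0).rstrip("*")
            b = translate(mutated, 0).rstrip("*")
            pi = pairwise_identity(a, b)
            assert pi.id_wrt_a == pytest.approx(100 * target, abs=2.0)
            assert b.startswith("M") and "*" not in b

    def test_unreachable_target_rejected(self, rng):
        cds = _random_cds(50, rng)
        with pytest.raises(ValueError):
            mutate_cds(cds, 1.5, rng)
        with pytest.raises(ValueError):
            mutate_cds(cds, 0.0, rng)


class TestTruncateAnnotation:
    def test_n_terminal(self):
        p = "M" + "A" * 99
        assert truncate_annotation(p, 20, "N") == p[20:]

    def test_c_terminal(self):
        p = "M" + "A" * 99
        assert truncate_annotation(p, 30, "C") == p[:70]

    def test_length_arithmetic(self):
        p = "M" + "K" * 558  # a 559-residue protein
        assert len(truncate_annotation(p, 169, "N")) == 390

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            truncate_annotation("MKT", 3, "N")
        with pytest.raises(ValueError):
            truncate_annotation("MKT", 0, "N")


class TestSimulateFamily:
    def test_mean_identity_concentrates(self, rng):
        cfg = SimConfig(
            n_genes=30, protein_len_range=(250, 350),
            species_identity={"sp": 0.9}, truncated_fraction=0.0, seed=3,
        )
        sim = simulate_family(cfg)
        ref = {r.id: r.seq for r in sim.reference_proteins}
        idents = [
            pairwise_identity(ref[p.id], p.seq).id_wrt_a
            for p in sim.species_proteins["sp"]
        ]
        assert 88.0 <= float(np.mean(idents)) <= 92.0

    def test_truncation_bookkeeping(self):
        cfg = small_cfg(truncated_fraction=0.25)
        sim = simulate_family(cfg)
        truncated = [g for g, gt in sim.truth.genes.items() if gt.truncated["sp"]]
        assert len(truncated) == round(0.25 * cfg.n_genes)
        for gid in truncated:
            gt = sim.truth.genes[gid]
            assert gt.annotated["sp"] != gt.true_protein["sp"]
        for gid, gt in sim.truth.genes.items():
            if not gt.truncated["sp"]:
                assert gt.annotated["sp"] == gt.true_protein["sp"]

    def test_paralogs_generated(self, rng):
        cfg = small_cfg(paralog_count=1, paralog_identity=0.7)
        sim = simulate_family(cfg)
        ids = {r.id for r in sim.reference_proteins}
        assert {"g0001", "g0001_p1"} <= ids
        assert sim.truth.genes["g0001_p1"].paralog_of == "g0001"


class TestFragmentTranscripts:
    def test_full_length_mode_keeps_complete_cds(self):
        cfg = small_cfg(p_expressed=1.0, full_length=True)
        sim = simulate_family(cfg)
        contigs = fragment_transcripts(
            sim.species_cds["sp"], cfg, sim.truth, "sp",
            np.random.default_rng(1),
        )
        by_gene = {}
        for c in contigs:
            by_gene.setdefault(c.id.rsplit("_c", 1)[0], []).append(c)
        cds_by_id = {r.id: r.seq for r in sim.species_cds["sp"]}
        for gid, cs in by_gene.items():
            assert any(
                c.seq == cds_by_id[gid] or reverse_complement(c.seq) == cds_by_id[gid]
                for c in cs
            )

    def test_unexpressed_genes_emit_nothing(self):
        cfg = small_cfg(p_expressed=0.0)
        sim = simulate_family(cfg)
        contigs = fragment_transcripts(
            sim.species_cds["sp"], cfg, sim.truth, "sp", np.random.default_rng(1)
        )
        assert contigs == []

    def test_contigs_are_substrings_of_their_cds(self):
        cfg = small_cfg(full_length=False, n_fragments=3)
        sim = simulate_family(cfg)
        contigs = fragment_transcripts(
            sim.species_cds["sp"], cfg, sim.truth, "sp", np.random.default_rng(2)
        )
        cds_by_id = {r.id: r.seq for r in sim.species_cds["sp"]}
        listed = {cid for gt in sim.truth.genes.values()
                  for cid in gt.contig_ids.get("sp", [])}
        assert listed == {c.id for c in contigs}
        for c in contigs:
            gene = c.id.rsplit("_c", 1)[0]
            assert (
                c.seq in cds_by_id[gene]
                or reverse_complement(c.seq) in cds_by_id[gene]
            )


class TestDeterminism:
    def test_same_seed_same_fixture_bytes(self, tmp_path):
        cfg = small_cfg(truncated_fraction=0.25)
        run_simulation(cfg, tmp_path / "a")
        run_simulation(cfg, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self, tmp_path):
        run_simulation(small_cfg(seed=1), tmp_path / "a")
        run_simulation(small_cfg(seed=2), tmp_path / "b")
        assert (tmp_path / "a" / "reference_cds.fasta").read_bytes() != (
            tmp_path / "b" / "reference_cds.fasta"
        ).read_bytes()

    def test_config_json_round_trip(self, tmp_path):
        cfg = small_cfg(paralog_count=2)
        p = cfg.to_json(tmp_path / "cfg.json")
        assert SimConfig.from_json(p) == cfg
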