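"""Six-frame translated search, alignment scores and hit statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from orthorefine.seqio import NucRecord, ProtRecord, reverse_complement, translate
from orthorefine.translate_search import (
    DEFAULT_PARAMS,
    Hsp,
    ScoringParams,
    bitscore,
    evalue,
    local_align,
    read_tabular,
    reverse_search,
    search,
    six_frame_translate,
    write_tabular,
)

from .conftest import random_dna, random_protein
from .oracles import revcomp, sw_score, translate_frame


class TestSixFrameTranslate:
    def test_plus_and_minus_zero_frames(self):
        contig = NucRecord("c", "ATGAAA")
        frames = {(f.strand, f.offset): f.prot for f in six_frame_translate(contig)}
        assert frames[("+", 0)] == "MK"
        assert frames[("-", 0)] == translate(reverse_complement("ATGAAA"), 0)

    def test_revcomp_symmetric_contig(self):
        seq = "ACGCGT"  # equals its own reverse complement
        assert reverse_complement(seq) == seq
        frames = six_frame_translate(NucRecord("c", seq))
        by = {(f.strand, f.offset): f.prot for f in frames}
        for off in range(3):
            assert by[("+", off)] == by[("-", off)]

    def test_matches_independent_per_frame_translation(self, rng):
        seq = random_dna(rng, 300, 300)
        frames = six_frame_translate(NucRecord("c", seq))
        assert len(frames) == 6
        for f in frames:
            source = seq if f.strand == "+" else revcomp(seq)
            assert f.prot == translate_frame(source, f.offset)

    def test_short_contig_yields_nothing(self):
        assert six_frame_translate(NucRecord("c", "AT")) == []

    def test_coord_map_round_trip(self, rng):
        seq = random_dna(rng, 60, 90)
        for f in six_frame_translate(NucRecord("c", seq)):
            for i in range(len(f.prot)):
                n0, n1 = f.nuc_interval(i, i + 1)
                assert n1 - n0 == 3
                assert 0 <= n0 < n1 <= len(seq)
                codon = seq[n0:n1] if f.strand == "+" else reverse_complement(seq[n0:n1])
                assert translate(codon, 0) == f.prot[i]


class TestLocalAlign:
    def test_exact_match_score(self):
        raw, qa, sa, q0, q1, s0, s1 = local_align("MKT", "MKT")
        assert raw == 15  # BLOSUM62 diagonal: M=5, K=5, T=5
        assert (qa, sa) == ("MKT", "MKT")
        assert (q0, q1, s0, s1) == (0, 3, 0, 3)

    def test_no_positive_pair(self):
        raw, qa, sa, *_ = local_align("AAAA", "CCCC")
        assert raw == 0 and qa == "" and sa == ""

    def test_unknown_matrix(self):
        with pytest.raises(ValueError):
            local_align("MK", "MK", ScoringParams(matrix="NOSUCH62"))

    def test_matches_exhaustive_dp_oracle(self, rng):
        for _ in range(60):
            q = random_protein(rng, 1, 12)
            s = random_protein(rng, 1, 12)
            assert local_align(q, s)[0] == sw_score(q, s)


class TestKarlinAltschul:
    def test_bitscore_hand_values(self):
        assert bitscore(0) == pytest.approx(4.6082, abs=1e-3)
        assert bitscore(100) == pytest.approx(43.128, abs=1e-2)

    def test_bitscore_monotone(self):
        assert bitscore(50) < bitscore(51)

    def test_evalue_identities(self):
        assert evalue(0.0, 100, 10**6) == pytest.approx(100 * 10**6)
        assert evalue(43.128, 100, 10**6) == pytest.approx(1.0404e-5, rel=1e-3)
        # one extra bit halves the expectation
        assert evalue(11.0, 50, 1000) == pytest.approx(evalue(10.0, 50, 1000) / 2)


def _planted_db(rng, n_contigs=10):
    """Contigs with one high-identity and one low-identity planted homologue."""
    from orthorefine.synth import _random_cds, mutate_cds

    cds = _random_cds(60, rng)
    query = ProtRecord("q", translate(cds, 0).rstrip("*"))
    contigs = [
        NucRecord("hit85", mutate_cds(cds, 0.85, rng)),
        NucRecord("hit60", mutate_cds(cds, 0.60, rng)),
    ]
    for i in range(n_contigs - 2):
        contigs.append(NucRecord(f"bg{i}", random_dna(rng, 150, 200)))
    return query, contigs


class TestSearch:
    def test_self_recovery(self, rng):
        seq = random_dna(rng, 150, 150)
        contigs = [NucRecord("src", seq)] + [
            NucRecord(f"bg{i}", random_dna(rng, 150, 150)) for i in range(3)
        ]
        prot = translate(seq, 0).replace("*", "W")  # avoid stops in the query
        query = ProtRecord("q", prot)
        hits = search(query, contigs, evalue_cutoff=1e3)
        assert hits[0].subject_id == "src"
        top = [h for h in hits if h.subject_id == "src"][0]
        assert top.pct_identity >= 98.0  # '*'->W substitutions may mismatch

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 120, 120)
        prot = translate(seq, 0).replace("*", "W")
        query = ProtRecord("q", prot)
        fwd = search(query, [NucRecord("c", seq)], evalue_cutoff=1e3)
        rev = search(
            query, [NucRecord("c", reverse_complement(seq))], evalue_cutoff=1e3
        )
        assert fwd[0].bitscore == rev[0].bitscore
        assert fwd[0].strand == "+" and rev[0].strand == "-"
        assert rev[0].sstart > rev[0].send

    def test_ranking_matches_planted_identities(self, rng):
        query, contigs = _planted_db(rng)
        hits = search(query, contigs)
        ranked = []
        for h in hits:
            if h.subject_id not in ranked:
                ranked.append(h.subject_id)
        assert ranked[:2] == ["hit85", "hit60"]

    def test_evalue_filter_and_monotonicity(self, rng):
        query, contigs = _planted_db(rng)
        loose = search(query, contigs, evalue_cutoff=1e5)
        strict = search(query, contigs, evalue_cutoff=1e-4)
        assert all(h.evalue <= 1e5 for h in loose)
        assert all(h.evalue <= 1e-4 for h in strict)
        assert len(strict) <= len(loose)
        strict_keys = {(h.subject_id, h.strand, h.frame_offset) for h in strict}
        loose_keys = {(h.subject_id, h.strand, h.frame_offset) for h in loose}
        assert strict_keys <= loose_keys

    def test_exhaustive_frame_oracle(self, rng):
        """Raw scores per (contig, strand, frame) equal the reference DP on
        small random instances, and the output ordering is the score order."""
        for _ in range(20):
            query = ProtRecord("q", random_protein(rng, 4, 12))
            contigs = [
                NucRecord(f"c{i}", random_dna(rng, 9, 60))
                for i in range(int(rng.integers(2, 6)))
            ]
            hits = search(query, contigs, evalue_cutoff=math.inf)
            expected = {}
            for c in contigs:
                for strand in "+-":
                    s = c.seq if strand == "+" else revcomp(c.seq)
                    for off in range(3):
                        if len(s) - off < 3:
                            continue
                        raw = sw_score(query.seq, translate_frame(s, off))
                        if raw > 0:
                            expected[(c.id, strand, off)] = raw
            got = {(h.subject_id, h.strand, h.frame_offset): h.raw_score for h in hits}
            assert got == expected
            keys = [(-h.bitscore, h.evalue, h.subject_id) for h in hits]
            assert keys == sorted(keys)


class TestReverseSearch:
    def test_exact_cds_recovery(self, rng):
        from orthorefine.synth import _random_cds

        cds = _random_cds(80, rng)
        prot = ProtRecord("P", translate(cds, 0).rstrip("*"))
        contig = NucRecord("c", cds)
        hits = reverse_search(contig, [prot], evalue_cutoff=1e3)
        assert hits[0].subject_id == "P"
        assert hits[0].pct_identity == 100.0

    def test_paralog_discrimination(self, rng):
        from orthorefine.synth import _random_cds, mutate_cds

        cds = _random_cds(80, rng)
        p = ProtRecord("P", translate(cds, 0).rstrip("*"))
        q = ProtRecord("Q", translate(mutate_cds(cds, 0.7, rng), 0).rstrip("*"))
        hits = reverse_search(NucRecord("c", cds), [p, q], evalue_cutoff=1e3)
        assert hits[0].subject_id == "P"

    def test_all_n_contig_finds_nothing(self):
        contig = NucRecord("c", "N" * 60)
        prot = ProtRecord("P", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        assert reverse_search(contig, [prot], evalue_cutoff=1e3) == []


class TestTabularFormat:
    def _hsps(self):
        return [
            Hsp("q1", "s1", 97.50, 40, 1, 0, 1, 40, 3, 122, 1.2e-20, 88.6, 300, "+", 2),
            Hsp("q1", "s2", 55.00, 20, 9, 1, 5, 24, 180, 121, 3.0e-5, 30.1, 95, "-", 1),
        ]

    def test_round_trip_is_bit_exact(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_tabular(self._hsps(), p1)
        write_tabular(read_tabular(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_reader_tolerates_extra_columns(self, tmp_path):
        p = tmp_path / "extra.tsv"
        line = "q\ts\t100.00\t10\t0\t0\t1\t10\t1\t30\t1e-08\t25.0\textra\tcols\n"
        p.write_text(line)
        (hsp,) = read_tabular(p)
        assert hsp.subject_id == "s" and hsp.bitscore == 25.0

    def test_strand_inferred_from_subject_order(self, tmp_path):
        p = tmp_path / "x.tsv"
        write_tabular(self._hsps(), p)
        a, b = read_tabular(p)
        assert a.strand == "+" and b.strand == "-"
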