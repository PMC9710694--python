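"""ORF loading, protein alignment, back-translation, quality, RBH pairing."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orfselect.codon_alignment import (
    OrfError,
    align_pair,
    alignment_score,
    back_translate,
    load_orfs,
    orf_from_nt,
    passes_quality,
    read_pairs_tsv,
    reciprocal_best_pairs,
)

from conftest import gotoh_score_oracle, random_sense_codons, write_fasta

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestOrfLoading:
    def test_terminal_stop_stripped(self, code):
        orf = orf_from_nt("x", "ATGGGGTAA", code)
        assert orf.nt == "ATGGGG"
        assert orf.aa == "MG"
        assert orf.length_aa == 2

    def test_internal_stop_rejected(self, code):
        with pytest.raises(OrfError, match="internal stop"):
            orf_from_nt("x", "ATGTAAGGGTGA", code)

    def test_length_not_multiple_of_three_rejected(self, code):
        with pytest.raises(OrfError, match="multiple of 3"):
            orf_from_nt("x", "ATGGGGTAAC", code)

    def test_load_orfs_skips_bad_records_with_log(self, tmp_path, caplog):
        path = write_fasta(
            tmp_path / "orfs.fasta",
            [("good", "ATGGGGTAA"), ("bad_stop", "ATGTAATTTTGA"), ("bad_len", "ATGGGGTAAC")],
        )
        with caplog.at_level("WARNING"):
            orfs = load_orfs(path)
        assert [o.id for o in orfs] == ["good"]
        assert "bad_stop" in caplog.text and "bad_len" in caplog.text

    def test_load_orfs_empty_file_errors(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(OrfError, match="no sequences"):
            load_orfs(empty)

    def test_gc_fraction_property(self, code):
        assert orf_from_nt("x", "ATGGGG", code).gc == pytest.approx(4 / 6)

    def test_pairs_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("# comment\na1\tb1\na2\tb2\n")
        assert read_pairs_tsv(p) == [("a1", "b1"), ("a2", "b2")]


class TestAlignPair:
    def test_identical_proteins(self, code):
        orf = orf_from_nt("x", "ATGGGG", code)
        pa = align_pair(orf, orf)
        assert pa.aligned_a == pa.aligned_b == "MG"
        assert pa.identity == 1.0

    def test_single_gap_toy_pair(self, code):
        # MAAG vs MAG: one gap column, identity over the 3 residue pairs
        a = orf_from_nt("a", "ATGGCTGCTGGT", code)
        b = orf_from_nt("b", "ATGGCTGGT", code)
        pa = align_pair(a, b)
        assert (pa.aligned_a + pa.aligned_b).count("-") == 1
        assert pa.identity == 1.0

    def test_score_matches_gotoh_oracle_on_random_pairs(self, rng):
        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(40):
            n, m = rng.integers(1, 13, size=2)
            a = "".join(AA[i] for i in rng.integers(len(AA), size=n))
            b = "".join(AA[i] for i in rng.integers(len(AA), size=m))
            assert alignment_score(a, b) == pytest.approx(
                gotoh_score_oracle(a, b, matrix)
            ), (a, b)


class TestBackTranslate:
    def test_identical_orfs_keep_all_columns(self, code, rng):
        nt = "".join(random_sense_codons(rng, 100, code))
        orf = orf_from_nt("x", nt, code)
        ca = back_translate(align_pair(orf, orf), orf, orf)
        assert ca.n_codons == 100

    def test_gap_column_excluded(self, code):
        a = orf_from_nt("a", "ATGGCTGCTGGT", code)
        b = orf_from_nt("b", "ATGGCTGGT", code)
        ca = back_translate(align_pair(a, b), a, b)
        assert ca.n_codons == 3

    def test_ambiguous_codon_column_excluded(self, code):
        from orfselect.codon_alignment import OrfRecord, ProteinAlignment

        a = OrfRecord(id="a", nt="ATGGGNTTT", aa="MXF")
        b = OrfRecord(id="b", nt="ATGGGGTTT", aa="MGF")
        pa = ProteinAlignment(aligned_a="MXF", aligned_b="MGF", score=0.0)
        ca = back_translate(pa, a, b)
        assert ca.n_codons == 2
        assert all("N" not in x + y for x, y in ca.columns)

    def test_lossless_on_gap_free_alignments(self, code):
        """Concatenating column codons reproduces each input sequence."""
        from orfselect.simulate import SimulationSpec, generate_pairs

        # simulated pairs have no indels, so their alignment is gap-free
        spec = SimulationSpec(n_codons=50, omega_true=0.2, expected_ds=0.2, n_pairs=1, seed=6)
        a, b = generate_pairs(spec, code)[0]
        pa = align_pair(a, b)
        assert "-" not in pa.aligned_a + pa.aligned_b
        ca = back_translate(pa, a, b)
        assert "".join(x for x, _ in ca.columns) == a.nt
        assert "".join(y for _, y in ca.columns) == b.nt

    def test_inconsistent_records_rejected(self, code):
        a = orf_from_nt("a", "ATGGGG", code)
        b = orf_from_nt("b", "ATGTTT", code)
        pa = align_pair(a, b)
        with pytest.raises(ValueError, match="does not match"):
            back_translate(pa, b, a)


class TestQualityFilter:
    def test_operating_regime_passes(self):
        v = passes_quality(0.92, 0.08)
        assert v.passed and v.reasons == ()

    def test_low_identity_fails(self):
        v = passes_quality(0.50, 0.1)
        assert not v.passed
        assert any("identity" in r for r in v.reasons)

    def test_high_ds_fails(self):
        v = passes_quality(0.95, 1.4)
        assert not v.passed
        assert any("d_S" in r for r in v.reasons)

    def test_boundaries_are_exclusive(self):
        assert not passes_quality(0.70, 0.5).passed  # identity must exceed 0.70
        assert not passes_quality(0.90, 1.0).passed  # d_S must stay below 1
        assert passes_quality(0.71, 0.99).passed


class TestReciprocalBestPairs:
    def _proteome(self, code, rng, n, tag):
        return [
            orf_from_nt(f"{tag}{i}", "".join(random_sense_codons(rng, 40, code)), code)
            for i in range(n)
        ]

    def test_identical_proteomes_map_to_themselves(self, code, rng):
        pa = self._proteome(code, rng, 4, "x")
        pb = [orf_from_nt(o.id.replace("x", "y"), o.nt, code) for o in pa]
        pairs = reciprocal_best_pairs(pa, pb)
        assert pairs == [(f"x{i}", f"y{i}") for i in range(4)]

    def test_symmetric_under_argument_swap(self, code, rng):
        pa = self._proteome(code, rng, 3, "a")
        pb = self._proteome(code, rng, 3, "b")
        fwd = reciprocal_best_pairs(pa, pb)
        rev = reciprocal_best_pairs(pb, pa)
        assert sorted((x, y) for y, x in rev) == fwd

    def test_unreciprocated_best_hit_excluded(self, code):
        # y0 is the best partner of both x0 and x1, so x1 stays unpaired
        x0 = orf_from_nt("x0", "ATGGCTGCTGCTGCT", code)  # MAAAA
        x1 = orf_from_nt("x1", "ATGGCTGCTGCTAGT", code)  # MAAAS
        y0 = orf_from_nt("y0", "ATGGCTGCTGCTGCT", code)  # MAAAA
        pairs = reciprocal_best_pairs([x0, x1], [y0])
        assert pairs == [("x0", "y0")]

    def test_empty_proteome_rejected(self, code):
        orf = orf_from_nt("x", "ATGGGG", code)
        with pytest.raises(ValueError):
            reciprocal_best_pairs([orf], [])
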