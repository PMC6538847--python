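"""Genome/annotation parsing, protein masses and degenerate motif counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboquant.annotation import (
    IUPAC_CODES,
    Genome,
    count_motif,
    protein_molecular_weight,
    read_annotation,
    read_genome,
    write_annotation,
)

WATER_DA = 18.0153


def brute_force_motif(seq: str, pattern: str) -> list[int]:
    """Independent sliding-window IUPAC matcher (per-window comparison)."""
    hits = []
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        ok = True
        for base, code in zip(seq[i:i + k], pattern):
            allowed = IUPAC_CODES[code] + ("N" if code == "N" else "")
            if base not in allowed:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


class TestReadGenome:
    def test_identity_readback(self, write_fasta):
        genome = read_genome(write_fasta([("c1", "GATC")]))
        assert genome.chromosomes == {"c1": "GATC"}

    def test_lowercase_normalized(self, write_fasta):
        genome = read_genome(write_fasta([("c1", "gatc")]))
        assert genome["c1"] == "GATC"

    def test_multiple_records_order_preserved(self, write_fasta):
        genome = read_genome(write_fasta([("a", "ACGT"), ("b", "GGCC")]))
        assert list(genome.chromosomes) == ["a", "b"]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            read_genome(path)

    def test_duplicate_ids_rejected(self, write_fasta):
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(write_fasta([("c1", "ACGT"), ("c1", "TTTT")]))

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            Genome({"c1": "ACGU"})


class TestReadAnnotation:
    def _gff(self, tmp_path, lines):
        path = tmp_path / "ann.gff3"
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return path

    def test_coordinate_convention(self, tmp_path, write_fasta):
        # GFF 1..9 (1-based inclusive) -> internal [0, 9)
        genome = read_genome(write_fasta([("c1", "ATGAAATGAT")]))
        gff = self._gff(tmp_path, ["c1\t.\tCDS\t1\t9\t.\t+\t0\tlocus_tag=g1"])
        (orf,) = read_annotation(gff, genome)
        assert (orf.start, orf.end) == (0, 9)
        assert orf.protein_sequence == "MK"
        assert orf.mol_weight == pytest.approx(
            protein_molecular_weight("MK"))

    def test_minus_strand_translated_from_reverse_complement(
            self, tmp_path, write_fasta):
        # revcomp of TCATTTCAT is ATGAAATGA -> protein MK
        genome = read_genome(write_fasta([("c1", "TCATTTCATG")]))
        gff = self._gff(tmp_path, ["c1\t.\tCDS\t1\t9\t.\t-\t0\tlocus_tag=g1"])
        (orf,) = read_annotation(gff, genome)
        assert orf.strand == "-"
        assert orf.protein_sequence == "MK"

    def test_length_not_multiple_of_three_skipped(self, tmp_path, write_fasta):
        genome = read_genome(write_fasta([("c1", "ATGAAATGAT")]))
        gff = self._gff(tmp_path, ["c1\t.\tCDS\t1\t7\t.\t+\t0\tlocus_tag=g1"])
        assert read_annotation(gff, genome) == []

    def test_missing_locus_tag_skipped(self, tmp_path, write_fasta):
        genome = read_genome(write_fasta([("c1", "ATGAAATGAT")]))
        gff = self._gff(tmp_path, ["c1\t.\tCDS\t1\t9\t.\t+\t0\tID=x"])
        assert read_annotation(gff, genome) == []

    def test_gff_roundtrip(self, tmp_path, write_fasta):
        genome = read_genome(write_fasta([("c1", "ATGAAATGA" + "ACGT" * 5)]))
        gff = self._gff(tmp_path, ["c1\t.\tCDS\t1\t9\t.\t+\t0\tlocus_tag=g1"])
        orfs = read_annotation(gff, genome)
        out = tmp_path / "out.gff3"
        write_annotation(out, orfs)
        again = read_annotation(out, genome)
        assert [(o.locus_tag, o.start, o.end, o.strand) for o in again] == \
               [(o.locus_tag, o.start, o.end, o.strand) for o in orfs]


class TestProteinMolecularWeight:
    @pytest.mark.parametrize("seq,expected", [
        ("G", 75.07),     # glycine residue + one water
        ("MG", 206.26),
    ])
    def test_reference_masses(self, seq, expected):
        assert protein_molecular_weight(seq) == pytest.approx(expected, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            protein_molecular_weight("")

    def test_unknown_residue_named_with_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 2"):
            protein_molecular_weight("MGB")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_additive_up_to_one_water(self, s1, s2):
        combined = protein_molecular_weight(s1 + s2)
        parts = protein_molecular_weight(s1) + protein_molecular_weight(s2)
        assert combined == pytest.approx(parts - WATER_DA, abs=1e-6)


class TestCountMotif:
    def test_simple_match(self):
        (mc,) = count_motif(Genome({"c1": "TTGAATCTT"}), "GAATC")
        assert mc.count == 1 and mc.positions == (2,)

    def test_degenerate_position(self):
        # GACTC and GATTC both satisfy GANTC (N is any base)
        (mc,) = count_motif(Genome({"c1": "GACTCGATTC"}), "GANTC")
        assert mc.count == 2 and mc.positions == (0, 5)
        # a window failing the final C does not count
        (mc2,) = count_motif(Genome({"c1": "GACTGGATTA"}), "GANTC")
        assert mc2.count == 0

    def test_overlapping_matches_counted(self):
        (mc,) = count_motif(Genome({"c1": "AAAA"}), "AA")
        assert mc.positions == (0, 1, 2)

    def test_genome_n_never_matches_concrete_code(self):
        # genome N under the pattern's concrete C never matches
        (mc,) = count_motif(Genome({"c1": "GANTCN"}), "GACTC")
        assert mc.count == 0

    def test_genome_n_matches_pattern_n(self):
        (mc,) = count_motif(Genome({"c1": "GANTCAA"}), "GANTC")
        assert mc.count == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            count_motif(Genome({"c1": "ACGT"}), "GAXTC")

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(10):
            n = int(rng.integers(50, 10_000))
            seq = "".join(rng.choice(list("ACGTN"), size=n,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            for pattern in ("GANTC", "RYN", "GGWCC"):
                (mc,) = count_motif(Genome({"c1": seq}), pattern)
                assert list(mc.positions) == brute_force_motif(seq, pattern)

    def test_palindromic_motif_counts_each_site_once(self, rng):
        # GANTC is its own reverse complement: a forward scan of both
        # strands finds the same physical sites, just mirrored.
        from Bio.Seq import Seq
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        (fwd,) = count_motif(Genome({"c1": seq}), "GANTC")
        (rev,) = count_motif(Genome({"c1": str(Seq(seq).reverse_complement())}),
                             "GANTC")
        assert fwd.count == rev.count
        mirrored = sorted(len(seq) - 5 - p for p in rev.positions)
        assert mirrored == list(fwd.positions)
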