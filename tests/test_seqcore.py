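import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rapscan import (
    NucSeq,
    ProteinSeq,
    RepeatAnnotation,
    RepeatInterval,
    STANDARD_CODE,
    nucleobase_density_profile,
    read_bed,
    read_fasta,
    reverse_complement,
    translate,
    translate_three_frames,
    write_bed,
    write_fasta,
)
from rapscan.seqcore import read_table, write_table

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestNucSeq:
    def test_rna_is_converted_to_dna_on_ingest(self):
        assert NucSeq(id="r", seq="acgu").seq == "ACGT"

    def test_empty_and_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            NucSeq(id="e", seq="")
        with pytest.raises(ValueError):
            NucSeq(id="b", seq="ACGZ")

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            NucSeq(id="s", seq="ACGT", strand="sense")


class TestGeneticCode:
    def test_sense_codon_and_stop_counts(self):
        assert len(STANDARD_CODE.sense_codons) == 61
        assert len(STANDARD_CODE.stop_codons) == 3
        assert sum(STANDARD_CODE.codon_multiplicity.values()) == 61

    def test_codon_multiplicity_groups(self):
        mult = STANDARD_CODE.codon_multiplicity
        assert all(mult[aa] == 6 for aa in "LSR")
        assert all(mult[aa] == 4 for aa in "AGPTV")
        assert mult["I"] == 3
        assert all(mult[aa] == 2 for aa in "CDEFHKNQY")
        assert all(mult[aa] == 1 for aa in "MW")


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("TATTCTCCTACTTCTCCTTCT", 0, "YSPTSPS"),
            ("ATG", 0, "M"),
            ("AATG", 1, "M"),
        ],
    )
    def test_known_translations(self, seq, frame, expected):
        assert translate(NucSeq(id="t", seq=seq), frame).seq == expected

    def test_three_frames(self):
        frames = translate_three_frames(NucSeq(id="t", seq="TATTCTC"))
        assert [p.seq for p in frames] == ["YS", "IL", "F"]

    def test_three_frames_rejects_short_input(self):
        with pytest.raises(ValueError, match="three frames"):
            translate_three_frames(NucSeq(id="t", seq="ACGT"))

    def test_n_codon_becomes_x(self):
        assert translate(NucSeq(id="n", seq="ATGNNN"), 0).seq == "MX"

    def test_stop_codon_becomes_star(self):
        assert translate(NucSeq(id="s", seq="TAA"), 0).seq == "*"

    @given(seq=st.text(alphabet="ACGT", min_size=5, max_size=60))
    def test_translation_length_identity(self, seq):
        ns = NucSeq(id="p", seq=seq)
        for frame, prot in enumerate(translate_three_frames(ns)):
            assert len(prot) == (len(seq) - frame) // 3


class TestReverseComplement:
    def test_examples(self):
        assert reverse_complement(NucSeq(id="x", seq="CACAC")).seq == "GTGTG"
        assert reverse_complement(NucSeq(id="n", seq="N")).seq == "N"

    def test_strand_flips(self):
        assert reverse_complement(NucSeq(id="x", seq="ACGT")).strand == "-"

    @given(seq=dna)
    def test_involution(self, seq):
        ns = NucSeq(id="x", seq=seq)
        assert reverse_complement(reverse_complement(ns)).seq == ns.seq


class TestDensityProfile:
    def test_examples(self):
        prof = nucleobase_density_profile(NucSeq(id="a", seq="AAAA"), "A", 2)
        assert prof.tolist() == [1.0, 1.0, 1.0]
        prof = nucleobase_density_profile(NucSeq(id="a", seq="ACGT"), "A", 4)
        assert prof.tolist() == [0.25]

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            nucleobase_density_profile(NucSeq(id="a", seq="ACGT"), "A", 5)

    @given(seq=st.text(alphabet="ACGT", min_size=4, max_size=40))
    def test_mirror_image_of_reverse_complement(self, seq):
        # base-B density of a sequence, read backwards, equals the
        # complementary-base density of the reverse complement
        ns = NucSeq(id="m", seq=seq)
        w = 3 if len(seq) >= 3 else 1
        fwd = nucleobase_density_profile(ns, "A", w)
        rev = nucleobase_density_profile(reverse_complement(ns), "T", w)
        assert np.allclose(fwd, rev[::-1])

    def test_mean_approximates_background(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=6000))
        prof = nucleobase_density_profile(NucSeq(id="u", seq=seq), "C", 50)
        assert abs(prof.mean() - 0.25) < 0.02


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        records = [
            NucSeq(id="a", seq="ACGT" * 40),
            NucSeq(id="b", seq="TTTT"),
            NucSeq(id="c", seq="NNNACGT"),
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path, kind="nuc")
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]

    def test_fasta_wraps_at_60_columns(self, tmp_path):
        path = tmp_path / "w.fasta"
        write_fasta([NucSeq(id="a", seq="A" * 130)], path)
        lines = path.read_text().splitlines()
        assert lines[1] == "A" * 60 and lines[3] == "A" * 10

    def test_protein_fasta_round_trip(self, tmp_path):
        path = tmp_path / "p.fasta"
        write_fasta([ProteinSeq(id="p", seq="YSPTSPS")], path)
        assert read_fasta(path, kind="protein")[0].seq == "YSPTSPS"

    def test_empty_fasta_gives_empty_list(self, tmp_path):
        path = tmp_path / "e.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_bed_round_trip_and_example_line(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t147\tACRO1\t.\t+\n")
        annot = read_bed(path)
        rec = annot.records[0]
        assert rec == RepeatInterval(chrom="chr1", start=0, end=147, family="ACRO1", strand="+")
        out = tmp_path / "o.bed"
        write_bed(annot, out)
        assert read_bed(out).records == annot.records

    def test_empty_bed_gives_empty_annotation(self, tmp_path):
        path = tmp_path / "e.bed"
        path.write_text("")
        assert len(read_bed(path)) == 0

    def test_malformed_bed_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\tfam\t.\t+\nchr1\t5\t3\tfam2\t.\t+\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(path)

    def test_table_round_trip(self, tmp_path):
        rows = [{"family": "ACRO1", "fold": 273.5}, {"family": "CA", "fold": 131.0}]
        path = tmp_path / "t.tsv"
        write_table(rows, path)
        back = read_table(path)
        assert back[0]["family"] == "ACRO1"
        assert float(back[0]["fold"]) == 273.5


class TestRepeatAnnotation:
    def test_same_family_same_strand_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RepeatAnnotation(records=[
                RepeatInterval("chr1", 0, 100, "fam", "+"),
                RepeatInterval("chr1", 50, 150, "fam", "+"),
            ])

    def test_family_bp_pools_strands(self):
        annot = RepeatAnnotation(records=[
            RepeatInterval("chr1", 0, 100, "fam", "+"),
            RepeatInterval("chr1", 200, 250, "fam", "-"),
        ])
        assert annot.family_bp() == {"fam": 150}
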