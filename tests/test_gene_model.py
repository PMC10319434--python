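"""Coordinate arithmetic, codon mapping, and consequence calling."""

from __future__ import annotations

import numpy as np
import pytest

from triocascade import (
    VariantRecord,
    call_consequence,
    codon_index,
    frameshift_new_stop_offset,
    load_gene_models,
    mad2l1bp_transcript,
    truncated_tail_length,
    write_gene_models,
)
from triocascade.gene_model import (
    NON_STOP_CODONS,
    STOP_CODONS,
    CoordinateError,
    TranscriptModel,
    translate_cds,
)


class TestGenomicToCdna:
    def test_exonic_offset(self, toy_plus_model):
        coord = toy_plus_model.genomic_to_cdna(110)
        assert (coord.cds_pos, coord.intron_offset) == (10, 0)

    def test_acceptor_offset_negative(self, toy_plus_model):
        coord = toy_plus_model.genomic_to_cdna(195)
        assert (coord.cds_pos, coord.intron_offset) == (31, -6)
        assert str(coord) == "c.31-6"

    def test_donor_offset_positive(self, toy_plus_model):
        coord = toy_plus_model.genomic_to_cdna(133)
        assert (coord.cds_pos, coord.intron_offset) == (30, 3)
        assert str(coord) == "c.30+3"

    def test_out_of_range(self, toy_plus_model):
        with pytest.raises(CoordinateError):
            toy_plus_model.genomic_to_cdna(100_000)

    @pytest.mark.parametrize("model_name", ["toy_plus_model", "toy_minus_model"])
    def test_roundtrip_identity_all_coding_positions(self, model_name, request):
        model = request.getfixturevalue(model_name)
        for gpos in list(range(101, 131)) + list(range(201, 231)):
            coord = model.genomic_to_cdna(gpos)
            assert model.cdna_to_genomic(coord) == gpos

    @pytest.mark.parametrize("model_name", ["toy_plus_model", "toy_minus_model"])
    def test_roundtrip_identity_intronic(self, model_name, request):
        model = request.getfixturevalue(model_name)
        for gpos in range(131, 201):
            coord = model.genomic_to_cdna(gpos)
            assert coord.intron_offset != 0
            assert model.cdna_to_genomic(coord) == gpos

    def test_minus_strand_direction(self, toy_minus_model):
        # first coding base in transcript order is the genomically-last base
        assert toy_minus_model.genomic_to_cdna(230).cds_pos == 1
        assert toy_minus_model.genomic_to_cdna(101).cds_pos == 60


class TestMad2l1bpFixture:
    """The committed transcript must reproduce the published coordinate pairs."""

    def test_cdna_differences_match_genomic_differences(self):
        m = mad2l1bp_transcript()
        c853 = m.genomic_to_cdna(43608202).cds_pos
        c541 = m.genomic_to_cdna(43607890).cds_pos
        c518 = m.genomic_to_cdna(43607867).cds_pos
        assert (c853, c541, c518) == (853, 541, 518)
        assert c853 - c541 == 43608202 - 43607890 == 312
        assert c541 - c518 == 43607890 - 43607867 == 23

    def test_deep_intronic_anchor(self):
        m = mad2l1bp_transcript()
        coord = m.genomic_to_cdna(43600837)
        assert (coord.cds_pos, coord.intron_offset) == (21, -94)

    def test_protein_length(self):
        assert mad2l1bp_transcript().protein_length == 306

    def test_no_internal_stops(self):
        m = mad2l1bp_transcript()
        aa = translate_cds(m.cds_sequence)
        assert "*" not in aa[:-1] and aa.endswith("*")


class TestCodonIndex:
    @pytest.mark.parametrize(
        "cds_pos,codon", [(853, 285), (541, 181), (518, 173), (1, 1), (3, 1), (4, 2)]
    )
    def test_published_and_boundary_values(self, cds_pos, codon):
        assert codon_index(cds_pos) == codon

    def test_agrees_with_triplet_scan(self):
        # oracle: walk positions counting completed triplets
        codon, within = 1, 0
        for cds_pos in range(1, 10_001):
            assert codon_index(cds_pos) == codon
            within += 1
            if within == 3:
                codon, within = codon + 1, 0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            codon_index(0)


class TestTruncatedTail:
    @pytest.mark.parametrize(
        "length,stop,lost", [(306, 285, 22), (306, 181, 126), (50, 1, 50), (50, 50, 1)]
    )
    def test_values(self, length, stop, lost):
        assert truncated_tail_length(length, stop) == lost

    def test_stop_beyond_protein_rejected(self):
        with pytest.raises(ValueError):
            truncated_tail_length(306, 307)


class TestCallConsequence:
    def test_stopgain_in_tiny_cds(self, tiny_cds_model):
        # codon 2 CGA -> TGA via c.4C>T at genomic 104
        v = VariantRecord(chrom="chrT", pos=104, ref="C", alt="T")
        call = call_consequence(v, tiny_cds_model)
        assert call.functional_class == "stopgain"
        assert call.codon == 2
        assert call.protein_change == "p.R2*"

    def test_missense_and_synonymous(self, tiny_cds_model):
        miss = call_consequence(VariantRecord(chrom="chrT", pos=105, ref="G", alt="T"), tiny_cds_model)
        assert miss.functional_class == "missense"
        syn = call_consequence(VariantRecord(chrom="chrT", pos=106, ref="A", alt="G"), tiny_cds_model)
        assert syn.functional_class == "synonymous"

    def test_frameshift_deletion_at_codon_2(self, tiny_cds_model):
        # delete c.4 (anchor at c.3): ref "GC" alt "G" at genomic 103
        v = VariantRecord(chrom="chrT", pos=103, ref="GC", alt="G")
        call = call_consequence(v, tiny_cds_model)
        assert call.functional_class == "frameshift_deletion"
        assert call.codon == 2

    def test_deep_intronic_prints_offset(self):
        m = mad2l1bp_transcript()
        v = VariantRecord(chrom="chr6", pos=43600837, ref="G", alt="A")
        call = call_consequence(v, m)
        assert call.functional_class == "intronic"
        assert call.cdna_change == "c.21-94G>A"

    def test_splice_window(self, toy_plus_model):
        inside = call_consequence(VariantRecord(chrom="chrT", pos=132, ref="A", alt="G"), toy_plus_model)
        assert inside.functional_class == "splicing"
        deeper = call_consequence(VariantRecord(chrom="chrT", pos=150, ref="A", alt="G"), toy_plus_model)
        assert deeper.functional_class == "intronic"

    def test_intergenic_outside_span(self, toy_plus_model):
        call = call_consequence(VariantRecord(chrom="chrT", pos=5000, ref="A", alt="G"), toy_plus_model)
        assert call.functional_class == "intergenic"

    def test_published_frameshift_name(self):
        m = mad2l1bp_transcript()
        v = VariantRecord(chrom="chr6", pos=43607866, ref="TT", alt="T")
        call = call_consequence(v, m)
        assert call.protein_change == "p.F173Sfs*4"
        assert call.cdna_change == "c.518delT"

    def test_degraded_call_without_cds_sequence(self, toy_plus_model):
        bare = TranscriptModel(
            transcript_id="BARE", gene="G", chrom="chrT", strand="+",
            exons=toy_plus_model.exons, cds_start=101, cds_end=230,
        )
        v = VariantRecord(chrom="chrT", pos=110, ref="A", alt="G")
        with pytest.warns(UserWarning):
            call = call_consequence(v, bare)
        assert call.protein_change is None


class TestFrameshiftOffset:
    def test_stop_as_third_novel_codon(self):
        # deleting c.4 of ATG|CAC|TGG|CTA|AAA|TAA shifts the frame to
        # ATG|ACT|GGC|TAA: two novel residues, then the stop (offset 3)
        model = TranscriptModel(
            transcript_id="FS", gene="G", chrom="chrT", strand="+",
            exons=[(101, 118)], cds_start=101, cds_end=118,
            cds_sequence="ATGCACTGGCTAAAATAA",
        )
        result = frameshift_new_stop_offset(model, 3, "GC", "G")
        assert result.stop_offset == 3
        assert not result.stop_at_first

    def test_immediate_stop_flagged(self):
        model = TranscriptModel(
            transcript_id="FS2", gene="G", chrom="chrT", strand="+",
            exons=[(101, 112)], cds_start=101, cds_end=112,
            cds_sequence="ATGCTAACCTGA",
        )
        # delete c.4 (anchor c.3): mutated reads ATG|TAA -> stop at first
        # novel codon, named nonsense-style
        result = frameshift_new_stop_offset(model, 3, "GC", "G")
        assert result.stop_at_first
        assert result.stop_offset == 1

    def test_matches_full_retranslation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_codons = int(rng.integers(10, 40))
            codons = [NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons)]
            codons[0] = "ATG"
            cds = "".join(codons) + "TAA"
            model = TranscriptModel(
                transcript_id="R", gene="G", chrom="chrT", strand="+",
                exons=[(1001, 1000 + len(cds))], cds_start=1001, cds_end=1000 + len(cds),
                cds_sequence=cds, utr3_sequence="TTAATTAATTAA",
            )
            cds_pos = int(rng.integers(4, len(cds) - 6))
            ref = cds[cds_pos - 1: cds_pos + 1]
            if ref[0] == ref[1]:
                continue  # would trim to a different key
            result = frameshift_new_stop_offset(model, cds_pos, ref, ref[0])
            # oracle: translate the mutated sequence codon by codon from the
            # first altered codon and find the stop directly
            mutated = cds[:cds_pos] + cds[cds_pos + 1:] + "TTAATTAATTAA"
            first = codon_index(cds_pos + 1)
            expected = None
            for k, start in enumerate(range((first - 1) * 3, len(mutated) - 2, 3), 1):
                if mutated[start:start + 3] in STOP_CODONS:
                    expected = k
                    break
            assert result.stop_offset == expected


class TestGeneModelIO:
    def test_tsv_fasta_round_trip(self, tmp_path, toy_plus_model, toy_minus_model):
        models = [toy_plus_model, toy_minus_model]
        write_gene_models(models, tmp_path / "gm.tsv", tmp_path / "cds.fa")
        back = load_gene_models(tmp_path / "gm.tsv", tmp_path / "cds.fa")
        assert len(back) == 2
        for orig, loaded in zip(models, back):
            assert loaded.transcript_id == orig.transcript_id
            assert loaded.exons == orig.exons
            assert loaded.cds_sequence == orig.cds_sequence
            assert loaded.utr3_sequence == orig.utr3_sequence
            assert loaded.strand == orig.strand
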