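"""Coding consequences: SNVs, in-frame deletions with 3' normalization,
frameshifts, and domain mapping — checked against brute-force re-translation."""

import pytest
from Bio.Seq import Seq

from mmescape import variant_consequence as vc


class TestCodonArithmetic:
    @pytest.mark.parametrize("pos,codon", [(80, 27), (1, 1), (3, 1), (4, 2), (100, 34)])
    def test_codon_of_cds_pos(self, pos, codon):
        assert vc.codon_of_cds_pos(pos) == codon

    def test_out_of_range(self, bcma_cds):
        with pytest.raises(ValueError):
            vc.codon_of_cds_pos(0)
        with pytest.raises(ValueError):
            vc.codon_of_cds_pos(len(bcma_cds.seq) + 1, bcma_cds)


class TestCodingSequenceValidation:
    def test_fixture_is_well_formed(self, bcma_cds):
        assert bcma_cds.seq.startswith("ATG")
        assert len(bcma_cds.seq) % 3 == 0
        assert bcma_cds.protein[26] == "R"           # Arg27
        assert bcma_cds.protein[28:30] == "SS"       # Ser29-Ser30
        assert bcma_cds.protein[31] == "T"           # Thr32
        assert bcma_cds.protein[32:34] == "PP"       # Pro33-Pro34

    @pytest.mark.parametrize("seq", ["ATGTAA" + "A", "TTGGCTTAA", "ATGGCTGCT"])
    def test_malformed_cds_rejected(self, seq):
        with pytest.raises(ValueError):
            vc.CodingSequence("g", seq)


class TestAnnotateSnv:
    def test_arg27pro(self, bcma_cds, bcma_domains):
        """c.80G>C turns the CGA codon 27 into CCA: p.Arg27Pro, extracellular."""
        cons = vc.annotate_snv(bcma_cds, 80, "C", bcma_domains)
        assert cons.consequence == "missense"
        assert cons.hgvs_p == "p.Arg27Pro"
        assert cons.hgvs_c == "c.80G>C"
        assert cons.domain == "extracellular"

    def test_synonymous_third_position(self, bcma_cds):
        # codon 27 CGA -> CGG both encode Arg
        cons = vc.annotate_snv(bcma_cds, 81, "G")
        assert cons.consequence == "synonymous"
        assert cons.hgvs_p == "p.Arg27="

    def test_nonsense_mid_cds(self):
        """A stop gained mid-CDS is a nonsense call (p.XTer), the class of
        truncating escape variants like p.Arg233Ter on a full transcript."""
        codons = ["ATG", "GCT", "CGA", "GCT", "TAA"]      # toy CDS
        cds = vc.CodingSequence("toy", "".join(codons))
        cons = vc.annotate_snv(cds, 7, "T")               # CGA -> TGA
        assert cons.consequence == "nonsense"
        assert cons.hgvs_p == "p.Arg3Ter"

    def test_alt_equal_ref_rejected(self, bcma_cds):
        with pytest.raises(ValueError):
            vc.annotate_snv(bcma_cds, 80, "G")

    def test_non_acgt_rejected(self, bcma_cds):
        with pytest.raises(ValueError):
            vc.annotate_snv(bcma_cds, 80, "N")

    def test_snv_then_reverse_restores_cds(self, bcma_cds):
        cons = vc.annotate_snv(bcma_cds, 80, "C")
        mutated = vc.CodingSequence(
            bcma_cds.gene, bcma_cds.seq[:79] + "C" + bcma_cds.seq[80:])
        back = vc.annotate_snv(mutated, 80, "G")
        assert mutated.seq[:79] + "G" + mutated.seq[80:] == bcma_cds.seq
        assert back.hgvs_p == "p.Pro27Arg"

    def test_all_snvs_match_brute_force_on_toy_cds(self):
        """Exhaustive 12-codon oracle: every possible SNV class agrees with a
        direct re-translation using an independent codon walk."""
        codons = ["ATG", "AAA", "CGA", "TGG", "TCT", "CCG",
                  "GAT", "TGC", "ATT", "GGG", "CAC", "TAA"]
        cds = vc.CodingSequence("toy", "".join(codons))
        for pos in range(1, len(cds.seq) + 1):
            ref = cds.seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = cds.seq[:pos - 1] + alt + cds.seq[pos:]
                old_p = str(Seq(cds.seq).translate())
                new_p = str(Seq(mutated).translate())
                idx = (pos - 1) // 3
                if new_p[idx] == old_p[idx]:
                    expected = "synonymous"
                elif new_p[idx] == "*" and old_p[idx] != "*":
                    expected = "nonsense"
                else:
                    expected = "missense"
                assert vc.annotate_snv(cds, pos, alt).consequence == expected, \
                    f"c.{pos}{ref}>{alt}"


class TestInframeDeletion:
    def test_pro34del(self, bcma_cds, bcma_domains):
        """c.98_100del removes one of the Pro33/Pro34 pair; HGVS 3' rule
        reports the most C-terminal equivalent residue."""
        cons = vc.annotate_inframe_del(bcma_cds, 98, 100, bcma_domains)
        assert cons.consequence == "inframe_del"
        assert cons.hgvs_p == "p.Pro34del"
        assert cons.domain == "extracellular"

    def test_ser30del(self, bcma_cds):
        cons = vc.annotate_inframe_del(bcma_cds, 87, 89)
        assert cons.hgvs_p == "p.Ser30del"

    def test_three_prime_normalization_invariance(self, bcma_cds):
        """Deleting either identical codon of a repeat yields the same p.
        string (Ser29/Ser30 share AGC; Pro33/Pro34 share CCA)."""
        assert vc.annotate_inframe_del(bcma_cds, 85, 87).hgvs_p == \
            vc.annotate_inframe_del(bcma_cds, 88, 90).hgvs_p == "p.Ser30del"
        assert vc.annotate_inframe_del(bcma_cds, 97, 99).hgvs_p == \
            vc.annotate_inframe_del(bcma_cds, 100, 102).hgvs_p == "p.Pro34del"

    def test_full_codon_in_non_repeat_context(self, bcma_cds):
        # codon 31 (AAT, Asn) has unique neighbors
        cons = vc.annotate_inframe_del(bcma_cds, 91, 93)
        assert cons.hgvs_p == "p.Asn31del"

    def test_multi_codon_deletion(self, bcma_cds):
        cons = vc.annotate_inframe_del(bcma_cds, 91, 96)   # Asn31 + Thr32
        assert cons.hgvs_p == "p.Asn31_Thr32del"

    def test_non_multiple_of_three_routes_to_frameshift(self, bcma_cds):
        cons = vc.annotate_inframe_del(bcma_cds, 98, 99)
        assert cons.consequence == "frameshift"


class TestFrameshift:
    def test_hand_computed_re_translation(self):
        """1-bp deletion in a toy CDS: the fs and Ter positions match a manual
        re-translation of the shifted frame."""
        #        M   K   R   W   S   stop-in-shifted-frame source
        codons = ["ATG", "AAA", "CGA", "TGG", "TCA", "GGC", "TAA"]
        cds = vc.CodingSequence("toy", "".join(codons))
        # delete c.7 (first base of codon 3): new seq ATG AAA GAT GGT CAG GCT AA
        cons = vc.annotate_frameshift(cds, 7, 7)
        # shifted translation: M K D G Q A -> first change at residue 3 (R->D)
        # no stop before the (now incomplete) end: flagged, not an error
        assert cons.consequence == "frameshift"
        assert cons.hgvs_p.startswith("p.Arg3Aspfs")
        assert cons.no_stop

    def test_shift_lands_on_immediate_stop(self):
        # deleting c.7 shifts codon 3 onto TAA: an immediate stop
        codons = ["ATG", "AAA", "CTA", "ACG", "TAA"]
        cds = vc.CodingSequence("toy", "".join(codons))
        cons = vc.annotate_frameshift(cds, 7, 7)
        assert cons.consequence == "frameshift"
        assert cons.hgvs_p == "p.Leu3Ter"
        assert not cons.no_stop

    def test_standard_and_absolute_ter_numbering(self):
        # CDS where the shifted frame hits a stop 3 codons downstream
        codons = ["ATG", "AAA", "CGA", "TGG", "CTG", "ATA", "ACC", "TAA"]
        cds = vc.CodingSequence("toy", "".join(codons))
        cons = vc.annotate_frameshift(cds, 10, 10)
        # manual: delete c.10 -> ATG AAA CGA GGC TGA ...: R3 unchanged,
        # W4->G, stop at codon 5 -> fsTer2 (standard), Ter5 (absolute)
        assert cons.hgvs_p == "p.Trp4GlyfsTer2"
        assert cons.hgvs_p_absolute == "p.Trp4GlyfsTer5"

    def test_multiple_of_three_routes_to_inframe(self, bcma_cds):
        cons = vc.annotate_frameshift(bcma_cds, 98, 100)
        assert cons.consequence == "inframe_del"


class TestDomainMap:
    def test_labels(self, bcma_domains):
        assert vc.domain_of_residue(27, bcma_domains) == "extracellular"
        assert vc.domain_of_residue(54, bcma_domains) == "extracellular"
        assert vc.domain_of_residue(55, bcma_domains) == "transmembrane"
        assert vc.domain_of_residue(100, bcma_domains) == "intracellular"

    def test_unannotated_gap(self):
        dm = vc.ProteinDomainMap(((1, 5, "a"), (10, 12, "b")))
        assert vc.domain_of_residue(7, dm) == "unannotated"

    def test_out_of_range(self, bcma_domains):
        with pytest.raises(ValueError):
            vc.domain_of_residue(0, bcma_domains)
        with pytest.raises(ValueError):
            vc.domain_of_residue(101, bcma_domains, protein_length=100)

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError):
            vc.ProteinDomainMap(((1, 5, "a"), (5, 9, "b")))


class TestCStringDispatch:
    @pytest.mark.parametrize("text,hgvs_p", [
        ("c.80G>C", "p.Arg27Pro"),
        ("c.98_100del", "p.Pro34del"),
        ("c.87_89del", "p.Ser30del"),
    ])
    def test_published_variants(self, bcma_cds, text, hgvs_p):
        assert vc.annotate_cds_change(bcma_cds, text).hgvs_p == hgvs_p

    def test_reference_mismatch_rejected(self, bcma_cds):
        with pytest.raises(ValueError, match="mismatch"):
            vc.annotate_cds_change(bcma_cds, "c.80A>C")

    def test_unsupported_notation(self, bcma_cds):
        with pytest.raises(ValueError):
            vc.annotate_cds_change(bcma_cds, "c.80_81insA")
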