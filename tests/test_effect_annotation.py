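import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import iscmscan as m
from iscmscan.effect_annotation import codon_one_sub_from

from conftest import oracle_effect, random_orf_genome


class TestMapToCodon:
    def test_plus_strand_arithmetic(self):
        genome = m.Genome({"c": "T" * 100 + "ATG" + "GCT" * 30 + "TAA" + "T" * 50})
        orf = m.OrfRecord("O", "c", 101, 196, "+")
        ci, off, codon = m.map_to_codon(orf, genome, 104)
        assert (ci, off, codon) == (2, 1, "GCT")

    def test_minus_strand_first_codon(self):
        # ORF on minus strand at [101,109]: genomic slice revcomp'd;
        # pos 109 is the first base of codon 1 on the coding strand.
        cds = "ATGTGGTAA"
        genome = m.Genome({"c": "T" * 100 + m.reverse_complement(cds) + "T" * 20})
        orf = m.OrfRecord("O", "c", 101, 109, "-")
        ci, off, codon = m.map_to_codon(orf, genome, 109)
        assert (ci, off, codon) == (1, 1, "ATG")

    def test_last_base_maps_to_last_codon_offset_3(self):
        genome = m.Genome({"c": "T" * 100 + "ATG" + "GCT" * 30 + "TAA" + "T" * 50})
        orf = m.OrfRecord("O", "c", 101, 196, "+")
        ci, off, _ = m.map_to_codon(orf, genome, 196)
        assert (ci, off) == (orf.n_codons, 3)

    def test_position_outside_orf_rejected(self):
        genome = m.Genome({"c": "ATGTAA" + "T" * 10})
        orf = m.OrfRecord("O", "c", 1, 6, "+")
        with pytest.raises(ValueError):
            m.map_to_codon(orf, genome, 7)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(n_codons=st.integers(3, 120), ci=st.integers(1, 120),
           off=st.integers(1, 3), minus=st.booleans(),
           flank=st.integers(0, 25))
    def test_codon_mapping_inverts_coordinate_arithmetic(
            self, n_codons, ci, off, minus, flank):
        """Converting (codon, offset) to a genomic position and mapping it
        back is the identity, on both strands and at any ORF placement."""
        assume(ci <= n_codons)
        cds = "ATG" + "GCT" * (n_codons - 2) + "TAA"
        genomic = m.reverse_complement(cds) if minus else cds
        genome = m.Genome({"c": "T" * flank + genomic + "TT"})
        start = flank + 1
        end = flank + len(cds)
        orf = m.OrfRecord("O", "c", start, end, "-" if minus else "+")
        cds_pos = (ci - 1) * 3 + off
        pos = end - (cds_pos - 1) if minus else start + cds_pos - 1
        got_ci, got_off, got_codon = m.map_to_codon(orf, genome, pos)
        assert (got_ci, got_off) == (ci, off)
        assert got_codon == cds[(ci - 1) * 3: ci * 3]


class TestTruncationAndNotation:
    @pytest.mark.parametrize("protein_len,codon_index,expected", [
        (306, 244, 62),   # W244TGA in a 306-residue protein
        (893, 887, 6),    # E887TAA in an 893-residue protein
        (224, 135, 89),   # Q135TAG in a 224-residue protein
        (571, 64, 507),   # E64TAA in a 571-residue protein
        (100, 100, 0),    # last residue mutated
    ])
    def test_truncation_examples(self, protein_len, codon_index, expected):
        assert m.truncation_length(protein_len, codon_index) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.truncation_length(100, 101)

    @pytest.mark.parametrize("ref_aa,idx,alt,expected", [
        ("Q", 135, "TAG", "Q135TAG"),
        ("E", 64, "TAA", "E64TAA"),
        ("W", 244, "TGA", "W244TGA"),
        ("H", 71, "L", "H71L"),
        ("d", 524, "n", "D524N"),
    ])
    def test_notation_grammar(self, ref_aa, idx, alt, expected):
        assert m.notation(ref_aa, idx, alt) == expected


class TestSingleSubstitutionReachable:
    @pytest.mark.parametrize("aa,stop,expected", [
        ("W", "TGA", True),   # TGG -> TGA
        ("W", "TAA", False),  # TGG differs from TAA at two positions
        ("Q", "TAA", True),   # CAA -> TAA
        ("Q", "TAG", True),   # CAG -> TAG
        ("K", "TAA", True),   # AAA -> TAA
        ("Y", "TAA", True),   # TAT/TAC -> TAA
        ("L", "TAA", True),   # TTA -> TAA
        ("F", "TAA", False),
        ("M", "TGA", False),
    ])
    def test_reachability(self, aa, stop, expected, code):
        assert m.single_substitution_reachable(aa, stop, code) is expected

    def test_matches_exhaustive_enumeration(self, code):
        """Cross-check against brute-force enumeration over all codons."""
        for aa, codons in code.aa_to_codons.items():
            if aa == "*":
                continue
            for stop in code.stop_codons:
                brute = any(
                    sum(a != b for a, b in zip(c, stop)) == 1 for c in codons
                )
                assert m.single_substitution_reachable(aa, stop, code) is brute

    def test_codon_one_sub_from_returns_valid_pair(self, code):
        codon, offset = codon_one_sub_from("W", "TGA", code)
        assert codon == "TGG" and offset == 3


class TestAnnotateVariant:
    def test_minus_strand_gaa_to_taa_is_nonsense(self, code):
        """GAA codon 64 on a minus-strand ORF converted to TAA: the genomic
        plus-strand change is C->A at the complementary position."""
        protein_len = 571
        n_codons = protein_len + 1
        codons = ["ATG"] + ["GAA"] * (protein_len - 1) + ["TAA"]
        cds = "".join(codons)
        genome = m.Genome({"c": "T" * 30 + m.reverse_complement(cds) + "T" * 30})
        orf = m.OrfRecord("YOR128C", "c", 31, 30 + len(cds), "-", gene_name="ADE2")
        # codon 64 base 1 (G on coding strand) -> T gives TAA
        cds_pos = 63 * 3 + 1
        pos = orf.end - (cds_pos - 1)
        assert genome.base("c", pos) == "C"  # complement of coding G
        variant = m.VariantRecord("c", pos, "C", "A", "G600")
        (ann,) = m.annotate_variant(variant, [orf], genome, code)
        assert ann.effect is m.SnpEffect.NONSENSE
        assert ann.notation == "E64TAA"
        assert ann.truncation_len == 507

    def test_intergenic_between_orfs(self, toy_genome, code):
        genome, orfs = toy_genome
        variant = m.VariantRecord("chrA", 5, "T", "A", "s1")
        anns = m.annotate_variant(variant, orfs, genome, code)
        assert len(anns) == 1
        assert anns[0].effect is m.SnpEffect.INTERGENIC

    def test_all_nine_mutants_of_tgg(self, code):
        """Brute-force enumeration of the 9 single-base mutants of TGG:
        exactly TGA and TAG are nonsense, the rest missense, none
        synonymous."""
        cds = "ATG" + "TGG" + "GAA" * 5 + "TAA"
        genome = m.Genome({"c": cds})
        orf = m.OrfRecord("O", "c", 1, len(cds), "+")
        outcomes = {}
        for off in range(3):
            pos = 4 + off  # codon 2 occupies [4,6]
            ref = genome.base("c", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = m.VariantRecord("c", pos, ref, alt, "s")
                (ann,) = m.annotate_variant(v, [orf], genome, code)
                outcomes[ann.alt_codon] = ann.effect
        assert len(outcomes) == 9
        nonsense = {c for c, e in outcomes.items() if e is m.SnpEffect.NONSENSE}
        assert nonsense == {"TGA", "TAG"}
        assert all(e is m.SnpEffect.MISSENSE for c, e in outcomes.items()
                   if c not in nonsense)

    def test_ref_mismatch_is_undetermined(self, toy_genome, code):
        genome, orfs = toy_genome
        variant = m.VariantRecord("chrA", 12, "C", "A", "s1")  # genome has T
        (ann,) = m.annotate_variant(variant, orfs, genome, code)
        assert ann.effect is m.SnpEffect.UNDETERMINED

    def test_n_in_codon_is_undetermined_not_synonymous(self, code):
        cds = "ATG" + "GNA" + "TAA"
        genome = m.Genome({"c": cds})
        orf = m.OrfRecord("O", "c", 1, 9, "+")
        v = m.VariantRecord("c", 4, "G", "A", "s")
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        assert ann.effect is m.SnpEffect.UNDETERMINED

    def test_start_codon_change_is_start_loss(self, code):
        cds = "ATGTGGTAA"
        genome = m.Genome({"c": cds})
        orf = m.OrfRecord("O", "c", 1, 9, "+")
        v = m.VariantRecord("c", 1, "A", "C", "s")
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        assert ann.effect is m.SnpEffect.START_LOSS

    def test_overlapping_orfs_get_one_record_each(self, code):
        cds = "ATGTGGGAACAAAAATAA"
        genome = m.Genome({"c": cds + "T" * 10})
        orf1 = m.OrfRecord("O1", "c", 1, 18, "+")
        orf2 = m.OrfRecord("O2", "c", 4, 18, "+")  # overlapping frame
        v = m.VariantRecord("c", 10, "C", "G", "s")
        anns = m.annotate_variant(v, [orf1, orf2], genome, code)
        assert sorted(a.orf_id for a in anns) == ["O1", "O2"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_orfs_match_brute_force(self, seed, strand, code):
        """On random 100-codon ORFs with random SNPs, the annotator agrees
        with an oracle that rebuilds the mutant CDS and diffs proteins."""
        rng = np.random.default_rng(seed)
        genome, orf = random_orf_genome(rng, n_codons=100, strand=strand)
        index = m.OrfIndex([orf])
        for _ in range(120):
            pos = int(rng.integers(orf.start, orf.end + 1))
            ref = genome.base("chr1", pos)
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            v = m.VariantRecord("chr1", pos, ref, alt, "s")
            (ann,) = m.annotate_variant(v, index, genome, code)
            expected_effect, expected_ci = oracle_effect(genome, orf, v, code)
            assert ann.effect is expected_effect, (v, ann)
            if expected_ci is not None:
                assert ann.codon_index == expected_ci

    @pytest.mark.parametrize("seed", [10, 11])
    def test_strand_invariance(self, seed, code):
        """Annotating a variant equals annotating the complemented variant
        against the reverse-complemented genome with mirrored coordinates."""
        rng = np.random.default_rng(seed)
        genome, orf = random_orf_genome(rng, n_codons=60, strand="+")
        length = genome.length("chr1")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_genome = m.Genome({"chr1": m.reverse_complement(genome.chromosomes["chr1"])})
        mirrored = m.OrfRecord(orf.orf_id, "chr1",
                               length - orf.end + 1, length - orf.start + 1, "-")
        for _ in range(60):
            pos = int(rng.integers(orf.start, orf.end + 1))
            ref = genome.base("chr1", pos)
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
            v = m.VariantRecord("chr1", pos, ref, alt, "s")
            v2 = m.VariantRecord("chr1", length - pos + 1, comp[ref], comp[alt], "s")
            (a1,) = m.annotate_variant(v, [orf], genome, code)
            (a2,) = m.annotate_variant(v2, [mirrored], rc_genome, code)
            assert a1.effect is a2.effect
            assert a1.codon_index == a2.codon_index
            assert a1.ref_codon == a2.ref_codon
            assert a1.alt_codon == a2.alt_codon
            assert a1.notation == a2.notation

    def test_nonsense_mutant_protein_length_identity(self, code):
        """For NONSENSE: mutant protein length = codon_index - 1 and
        truncation + (codon_index - 1) + 1 = protein length."""
        rng = np.random.default_rng(5)
        genome, orf = random_orf_genome(rng, n_codons=80, strand="+")
        index = m.OrfIndex([orf])
        found = 0
        for pos in range(orf.start, orf.end + 1):
            ref = genome.base("chr1", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = m.VariantRecord("chr1", pos, ref, alt, "s")
                (ann,) = m.annotate_variant(v, index, genome, code)
                if ann.effect is not m.SnpEffect.NONSENSE:
                    continue
                found += 1
                mutant = (genome.chromosomes["chr1"][: pos - 1] + alt
                          + genome.chromosomes["chr1"][pos:])
                mutant_cds = m.extract_cds(m.Genome({"chr1": mutant}), orf)
                protein = m.translate(mutant_cds, code)
                assert protein.index("*") == ann.codon_index - 1
                assert (ann.truncation_len + (ann.codon_index - 1) + 1
                        == orf.protein_length)
        assert found > 0


class TestStopLossScan:
    def _stop_orf(self, downstream: str, strand="+"):
        cds = "ATGTGGTAA"
        if strand == "+":
            chrom = "GG" + cds + downstream
            orf = m.OrfRecord("O", "c", 3, 11, "+")
        else:
            chrom = m.reverse_complement(downstream) + m.reverse_complement(cds) + "GG"
            orf = m.OrfRecord("O", "c", len(downstream) + 1,
                              len(downstream) + 9, "-")
        return m.Genome({"c": chrom}), orf

    def test_stop_to_stop_is_retained_extension_zero(self, code):
        genome, orf = self._stop_orf("TTTTTT")
        # TAA -> TAG: last base A->G
        v = m.VariantRecord("c", 11, "A", "G", "s")
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        assert ann.effect is m.SnpEffect.STOP_RETAINED
        report = m.scan_stop_loss(ann, genome, orf, code)
        assert report.extension_codons == 0 and report.terminator_found

    def test_stop_loss_extension_counts_codons_to_next_stop(self, code):
        # 5 sense codons then TGA downstream
        genome, orf = self._stop_orf("GCT" * 5 + "TGA" + "TTT")
        v = m.VariantRecord("c", 9, "T", "C", "s")  # TAA -> CAA
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        assert ann.effect is m.SnpEffect.STOP_LOSS
        report = m.scan_stop_loss(ann, genome, orf, code)
        assert report.extension_codons == 5 and report.terminator_found

    def test_stop_loss_minus_strand(self, code):
        genome, orf = self._stop_orf("GCT" * 3 + "TAG", strand="-")
        # natural stop codon 1st base on coding strand is at genomic orf.start+2
        pos = orf.start + 2
        assert genome.base("c", pos) == "A"  # complement of coding T
        v = m.VariantRecord("c", pos, "A", "G", "s")  # coding TAA -> CAA
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        assert ann.effect is m.SnpEffect.STOP_LOSS
        report = m.scan_stop_loss(ann, genome, orf, code)
        assert report.extension_codons == 3 and report.terminator_found

    def test_no_terminator_before_chromosome_end_flagged(self, code):
        genome, orf = self._stop_orf("GCTGCTGC")  # no in-frame stop, ragged end
        v = m.VariantRecord("c", 9, "T", "C", "s")
        (ann,) = m.annotate_variant(v, [orf], genome, code)
        report = m.scan_stop_loss(ann, genome, orf, code)
        assert not report.terminator_found
        assert report.extension_codons == 2
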