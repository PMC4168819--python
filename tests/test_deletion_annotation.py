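"""HGVS deletion parsing, consequence annotation, in-silico PCR."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from homdel.deletion_annotation import (
    AssayFailureError,
    DeletionDescription,
    HgvsParseError,
    PrimerPair,
    annotate_deletion,
    classify_pcr_genotype,
    format_hgvs_c_del,
    in_silico_pcr,
    parse_hgvs_c_del,
    write_consequence_tsv,
    write_consequence_vcf,
)
from homdel.gene_model import CdsCoordinate
from homdel.synthetic_data import CANONICAL_DELETION, apply_deletion

LONGRANGE = PrimerPair("chrG", (1_002_300, 1_002_319), (1_005_421, 1_005_440))
EXON6_INTERNAL = PrimerPair("chrG", (1_004_140, 1_004_159), (1_004_300, 1_004_319))


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "text",
        ["c.294+139_531+478del", "c.294 + 139_531 + 478del"],
    )
    def test_parse_with_and_without_journal_whitespace(self, canonical, text):
        _, model = canonical
        d = parse_hgvs_c_del(text, model)
        assert d.start == CdsCoordinate(294, 139)
        assert d.end == CdsCoordinate(531, 478)
        assert format_hgvs_c_del(d) == "c.294+139_531+478del"

    def test_plain_exonic_deletion(self, canonical):
        _, model = canonical
        d = parse_hgvs_c_del("c.10_12del", model)
        assert (d.start, d.end) == (CdsCoordinate(10), CdsCoordinate(12))

    @pytest.mark.parametrize(
        "text",
        [
            "c.531+478_294+139del",  # reversed
            "g.100_200del",
            "c.10_12dup",
            "c.12del",
        ],
    )
    def test_malformed_or_reversed_rejected(self, canonical, text):
        _, model = canonical
        with pytest.raises(HgvsParseError):
            parse_hgvs_c_del(text, model)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_parse_format_round_trip_on_generated_deletions(self, canonical, seed):
        _, model = canonical
        rng = np.random.default_rng(seed)

        def random_coord():
            base = int(rng.integers(1, model.cds_length + 1))
            if rng.random() < 0.5:
                return CdsCoordinate(base)
            # anchor on a random exon boundary with a legal intronic offset
            bounds = [294, 295, 60, 61, 120, 121, 180, 181, 240, 241, 531, 532]
            base = int(rng.choice(bounds))
            intron = {294: 1770, 531: 1000}.get(base, 500)
            off = int(rng.integers(1, intron + 1))
            sign = 1 if base in {60, 120, 180, 240, 294, 531} else -1
            return CdsCoordinate(base, sign * off)

        a, b = random_coord(), random_coord()
        if model.cds_to_genomic(a) > model.cds_to_genomic(b):
            a, b = b, a
        text = format_hgvs_c_del(DeletionDescription(a, b))
        assert format_hgvs_c_del(parse_hgvs_c_del(text, model)) == text


class TestAnnotateDeletion:
    def test_canonical_deletion_full_consequence(self, canonical):
        genome, model = canonical
        d = parse_hgvs_c_del("c.294+139_531+478del", model)
        cons = annotate_deletion(d, model, genome)
        assert (cons.genomic_start, cons.genomic_end) == CANONICAL_DELETION
        assert cons.total_length == 2347
        assert cons.coding_bases_removed == 237
        assert cons.intronic_bases_removed == 2110
        assert cons.in_frame
        assert cons.protein_hgvs == "p.Tyr99_Glu177del"
        assert (cons.first_residue, cons.last_residue) == (99, 177)
        assert (cons.wt_protein_length, cons.mut_protein_length) == (447, 368)

    def test_canonical_deletion_unchanged_by_3prime_normalization(self, canonical):
        genome, model = canonical
        d = parse_hgvs_c_del("c.294+139_531+478del", model)
        plain = annotate_deletion(d, model, genome)
        normalized = annotate_deletion(d, model, genome, normalize_3prime=True)
        assert (normalized.genomic_start, normalized.genomic_end) == (
            plain.genomic_start,
            plain.genomic_end,
        )

    def test_single_codon_deletion(self, canonical):
        genome, model = canonical
        cons = annotate_deletion(
            parse_hgvs_c_del("c.295_297del", model), model, genome
        )
        assert cons.coding_bases_removed == 3
        assert cons.in_frame
        assert cons.protein_hgvs == "p.Tyr99del"
        assert cons.mut_protein_length == 446

    def test_frameshift_deletion_flagged(self, canonical):
        genome, model = canonical
        cons = annotate_deletion(
            parse_hgvs_c_del("c.295_296del", model), model, genome
        )
        assert cons.coding_bases_removed == 2
        assert not cons.in_frame
        assert cons.frameshift
        assert cons.protein_hgvs == "fs"

    def test_non_codon_aligned_in_frame_gets_junction_flag(self, canonical):
        genome, model = canonical
        cons = annotate_deletion(
            parse_hgvs_c_del("c.296_298del", model), model, genome
        )
        assert cons.in_frame
        assert cons.junction
        assert cons.protein_hgvs is None
        assert cons.mut_protein_length == 446

    @pytest.mark.parametrize(
        "text, reason",
        [
            ("c.1_6del", "initiator"),
            ("c.1340_1344del", "terminator"),
        ],
    )
    def test_terminal_codon_deletions_flagged_unsupported(
        self, canonical, text, reason
    ):
        genome, model = canonical
        cons = annotate_deletion(parse_hgvs_c_del(text, model), model, genome)
        assert cons.unsupported is not None and reason in cons.unsupported
        assert cons.protein_hgvs is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_codon_aligned_deletions_shorten_protein_by_codons_removed(
        self, canonical, seed
    ):
        genome, model = canonical
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(1, 100))
        first = int(rng.integers(2, 448 - n_codons))  # keep initiator/stop
        c_lo, c_hi = (first - 1) * 3 + 1, (first - 1 + n_codons) * 3
        cons = annotate_deletion(
            parse_hgvs_c_del(f"c.{c_lo}_{c_hi}del", model), model, genome
        )
        assert cons.in_frame
        assert cons.wt_protein_length - cons.mut_protein_length == (
            cons.coding_bases_removed // 3
        )
        assert cons.first_residue == first
        assert cons.last_residue == first + n_codons - 1

    def test_total_length_matches_bases_missing_from_mutant_sequence(self, canonical):
        genome, model = canonical
        d = parse_hgvs_c_del("c.294+139_531+478del", model)
        cons = annotate_deletion(d, model, genome)
        allele = apply_deletion(
            genome, model.chrom, cons.genomic_start, cons.genomic_end
        )
        wt_len = len(genome.sequence(model.chrom))
        assert wt_len - len(allele.sequence(model.chrom)) == cons.total_length


class TestInSilicoPcr:
    def test_wild_type_longrange_product(self, canonical):
        genome, _ = canonical
        assert in_silico_pcr(genome, LONGRANGE) == 3141  # 1,005,440-1,002,300+1

    def test_deleted_allele_shortens_product_by_deletion_length(self, canonical):
        genome, _ = canonical
        mut = apply_deletion(genome, "chrG", *CANONICAL_DELETION)
        assert in_silico_pcr(mut, LONGRANGE) == 794
        assert in_silico_pcr(genome, LONGRANGE) - in_silico_pcr(mut, LONGRANGE) == (
            mut.deleted_length
        )

    def test_exon_internal_primers_fail_on_deleted_allele(self, canonical):
        genome, _ = canonical
        mut = apply_deletion(genome, "chrG", *CANONICAL_DELETION)
        assert in_silico_pcr(genome, EXON6_INTERNAL) == 180
        assert in_silico_pcr(mut, EXON6_INTERNAL) is None

    def test_primer_over_breakpoint_yields_no_product(self, canonical):
        genome, _ = canonical
        mut = apply_deletion(genome, "chrG", *CANONICAL_DELETION)
        straddling = PrimerPair(
            "chrG", (1_002_475, 1_002_494), (1_005_421, 1_005_440)
        )
        assert in_silico_pcr(mut, straddling) is None

    def test_primer_pair_validation(self):
        with pytest.raises(ValueError, match="15-35"):
            PrimerPair("c", (100, 105), (300, 320))
        with pytest.raises(ValueError, match="5'"):
            PrimerPair("c", (300, 320), (100, 119))


class TestGenotypeClassification:
    def test_three_genotype_classes(self, canonical):
        genome, _ = canonical
        mut = apply_deletion(genome, "chrG", *CANONICAL_DELETION)
        combos = [
            ((genome, genome), "wild_type"),
            ((genome, mut), "carrier"),
            ((mut, mut), "homozygous_deleted"),
        ]
        for alleles, expected in combos:
            e6 = [in_silico_pcr(a, EXON6_INTERNAL) for a in alleles]
            lr = [in_silico_pcr(a, LONGRANGE) for a in alleles]
            assert classify_pcr_genotype(e6, lr) == expected

    def test_no_product_in_either_assay_is_assay_failure(self):
        with pytest.raises(AssayFailureError):
            classify_pcr_genotype([None, None], [None, None])


class TestReportOutput:
    def test_tsv_and_symbolic_vcf_outputs(self, canonical, tmp_path):
        genome, model = canonical
        cons = annotate_deletion(
            parse_hgvs_c_del("c.294+139_531+478del", model), model, genome
        )
        tsv = tmp_path / "cons.tsv"
        write_consequence_tsv(cons, tsv)
        header, row = tsv.read_text().splitlines()
        assert dict(zip(header.split("\t"), row.split("\t")))["total_length"] == "2347"

        vcf = tmp_path / "cons.vcf"
        write_consequence_vcf(cons, genome, vcf)
        with pysam.VariantFile(str(vcf)) as vf:
            rec = next(iter(vf))
            assert rec.info["SVTYPE"] == "DEL"
            assert rec.info["SVLEN"] == -2347
            assert rec.stop == cons.genomic_end
            assert rec.alts == ("<DEL>",)
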