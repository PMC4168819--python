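"""Filter cascade stages, repeat-context flagging, and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homdel.gene_model import GenomeSequence
from homdel.roh_mapping import RohRegion
from homdel.synthetic_data import (
    DEFAULT_SHARED_SEGMENTS,
    Segment,
    VcfComposition,
    simulate_vcf,
)
from homdel.variant_filter import (
    REPEAT_FLAG,
    FilterReport,
    FilterStage,
    VariantRecord,
    filter_functional,
    filter_known,
    flag_repeat_context,
    read_vcf,
    restrict_to_regions,
    run_cascade,
    write_survivors_vcf,
)

CANDIDATE_REGIONS = [
    RohRegion(chrom="chr1", start=11_698_902, end=26_171_473),
    RohRegion(chrom="chr4", start=71_230_491, end=83_403_217),
]


def rec(chrom="chr1", pos=15_000_000, ref="A", alt="G", **kw):
    defaults = dict(pass_flag=True)
    defaults.update(kw)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


class TestRegionRestriction:
    def test_containment_against_printed_bounds(self):
        kept = restrict_to_regions([rec(pos=15_000_000)], CANDIDATE_REGIONS)
        assert len(kept) == 1

    def test_wrong_chromosome_and_nonpass_dropped(self):
        records = [
            rec(chrom="chr2", pos=100),
            rec(pos=15_000_000, pass_flag=False),
            rec(pos=11_698_902),  # inclusive left bound
            rec(pos=26_171_473),  # inclusive right bound
            rec(pos=26_171_474),
        ]
        kept = restrict_to_regions(records, CANDIDATE_REGIONS)
        assert [v.pos for v in kept] == [11_698_902, 26_171_473]


class TestKnownPolymorphismFilter:
    @pytest.mark.parametrize(
        "db129, maf, kept",
        [
            (False, 0.005, True),
            (True, None, False),
            (False, 0.01, False),  # threshold inclusive
            (False, None, True),  # unknown MAF retained
            (False, 0.0099, True),
        ],
    )
    def test_truth_table(self, db129, maf, kept):
        v = rec(in_dbsnp129=db129, maf_dbsnp137=maf)
        assert (filter_known([v]) == [v]) is kept


class TestFunctionalFilter:
    @pytest.mark.parametrize(
        "fclass, kept",
        [
            ("nonsynonymous", True),
            ("exonic_indel", True),
            ("splice_consensus", True),
            ("synonymous", False),
            ("intronic", False),
            ("intergenic", False),
            ("other", False),
        ],
    )
    def test_retained_classes(self, fclass, kept):
        v = rec(functional_class=fclass)
        assert (filter_functional([v]) == [v]) is kept

    def test_known_and_functional_stages_commute(self):
        rng = np.random.default_rng(1)
        classes = ["nonsynonymous", "synonymous", "exonic_indel", "intronic"]
        records = [
            rec(
                pos=12_000_000 + i,
                in_dbsnp129=bool(rng.random() < 0.4),
                maf_dbsnp137=float(rng.uniform(0, 0.05)) if rng.random() < 0.5
                else None,
                functional_class=str(rng.choice(classes)),
            )
            for i in range(200)
        ]
        ab = filter_functional(filter_known(records))
        ba = filter_known(filter_functional(records))
        assert ab == ba


class TestRepeatContextFlag:
    def genome_with(self, context, start=1_000):
        return GenomeSequence({"chr1": context}, {"chr1": start})

    def test_cgg_insertion_in_cgg_tract_flagged(self):
        # anchor at pos, (CGG)8 tract immediately 3' of it
        genome = self.genome_with("TTACGTAC" + "A" + "CGG" * 8 + "TTGACGTA")
        pos = 1_008  # the anchor 'A'
        v = rec(pos=pos, ref="A", alt="A" + "CGG" * 5)
        assert flag_repeat_context(v, genome) is True

    def test_nonrepetitive_insertion_not_flagged(self):
        genome = self.genome_with("TTACGTACGGATCCATTGACGTAGCTAGCATG")
        v = rec(pos=1_010, ref="G", alt="GACT")
        assert flag_repeat_context(v, genome) is False

    def test_at_deletion_in_at_tract_flagged(self):
        genome = self.genome_with("GCGTACGC" + "G" + "AT" * 10 + "GCCGTAGC")
        v = rec(pos=1_008, ref="G" + "ATATAT", alt="G")
        assert flag_repeat_context(v, genome) is True

    def test_snv_not_applicable(self):
        genome = self.genome_with("ACGT" * 10)
        assert flag_repeat_context(rec(ref="A", alt="G"), genome) is None

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_brute_force_unit_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        context = "".join(rng.choice(list("ACGT"), size=200))
        # half the time, embed a planted tandem tract after the anchor
        anchor_idx = 100
        unit_len = int(rng.integers(1, 7))
        unit = "".join(rng.choice(list("ACGT"), size=unit_len))
        if rng.random() < 0.5:
            copies = int(rng.integers(2, 9))
            context = (
                context[: anchor_idx + 1]
                + unit * copies
                + context[anchor_idx + 1 + unit_len * copies :]
            )
        n_units = int(rng.integers(1, 4))
        genome = GenomeSequence({"chr1": context}, {"chr1": 1})
        pos = anchor_idx + 1  # 1-based anchor
        v = rec(
            pos=pos,
            ref=context[anchor_idx],
            alt=context[anchor_idx] + unit * n_units,
        )
        got = flag_repeat_context(v, genome, unit_max=6, min_copies=4)
        assert got == brute_force_repeat_flag(
            context, anchor_idx, unit * n_units, unit_max=6, min_copies=4
        )


def brute_force_repeat_flag(context, anchor_idx, changed, unit_max, min_copies):
    """Naive re-derivation: try every unit decomposition of the changed
    sequence and count tract copies around the anchor by string scanning."""
    for u in range(1, min(unit_max, len(changed)) + 1):
        if len(changed) % u or changed != changed[:u] * (len(changed) // u):
            continue
        unit = changed[:u]
        copies = 0
        i = anchor_idx + 1
        while context[i : i + u] == unit:
            copies += 1
            i += u
        i = anchor_idx + 1 - u
        while i >= 0 and context[i : i + u] == unit:
            copies += 1
            i -= u
        if copies >= min_copies:
            return True
    return False


@pytest.fixture(scope="module")
def small_vcf(tmp_path_factory):
    """A scaled-down simulated VCF over one small candidate region."""
    out = tmp_path_factory.mktemp("vcf")
    regions = [Segment("chr1", 16_500_000, 17_500_000)]
    comp = VcfComposition(
        n_known_common=60, n_rare_silent=8, n_rare_functional=2,
        n_repeat_insertion=1, n_nonpass=5, n_outside=6,
    )
    path, truth, genome = simulate_vcf(
        regions, out / "v.vcf", composition=comp, seed=11, margin=300_000
    )
    return path, truth, genome, regions


class TestCascade:
    def test_counts_and_survivors_match_generator_truth(self, small_vcf):
        path, truth, genome, segments = small_vcf
        regions = [RohRegion(chrom=s.chrom, start=s.start, end=s.end)
                   for s in segments]
        report = run_cascade(path, regions, genome=genome)
        report.check_consistent()
        counts = {s.name: (s.n_in, s.n_out) for s in report.stages}
        assert counts["restrict_to_regions"] == (82, 71)
        assert counts["filter_known"] == (71, 11)
        assert counts["filter_functional"] == (11, 3)
        truth_surviving = {
            (r["chrom"], r["pos"])
            for r in truth.variant_truth
            if r["category"] in {"rare_functional", "repeat_insertion"}
        }
        assert {(v.chrom, v.pos) for v in report.survivors} == truth_surviving
        flagged = {v.pos for v in report.survivors if REPEAT_FLAG in v.flags}
        planted = {
            r["pos"]
            for r in truth.variant_truth
            if r["category"] == "repeat_insertion"
        }
        assert flagged == planted

    def test_strictly_decreasing_counts_on_default_composition(self, small_vcf):
        path, _, genome, segments = small_vcf
        regions = [RohRegion(chrom=s.chrom, start=s.start, end=s.end)
                   for s in segments]
        report = run_cascade(path, regions, genome=genome)
        filtering = report.stages[:3]
        assert all(s.n_out < s.n_in for s in filtering)

    def test_empty_vcf_gives_zero_counts(self, tmp_path):
        comp = VcfComposition(0, 0, 0, 0, 0, 0)
        path, _, genome = simulate_vcf(
            [Segment("chr1", 1_000_000, 1_100_000)],
            tmp_path / "empty.vcf",
            composition=comp,
            seed=0,
            margin=50_000,
        )
        report = run_cascade(path, [RohRegion(chrom="chr1", start=1, end=2)],
                             genome=genome)
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)
        assert report.survivors == []

    def test_only_common_snvs_leave_no_survivors(self, tmp_path):
        comp = VcfComposition(40, 0, 0, 0, 0, 0)
        seg = Segment("chr1", 1_000_000, 1_200_000)
        path, _, genome = simulate_vcf(
            [seg], tmp_path / "common.vcf", composition=comp, seed=2,
            margin=50_000,
        )
        report = run_cascade(
            path, [RohRegion(chrom=seg.chrom, start=seg.start, end=seg.end)],
            genome=genome,
        )
        assert report.stages[0].n_out == 40
        assert report.survivors == []

    def test_survivor_vcf_output_readable_and_flagged(self, small_vcf, tmp_path):
        import pysam

        path, _, genome, segments = small_vcf
        regions = [RohRegion(chrom=s.chrom, start=s.start, end=s.end)
                   for s in segments]
        report = run_cascade(path, regions, genome=genome)
        _, header = read_vcf(path)
        out = tmp_path / "survivors.vcf"
        write_survivors_vcf(report, header, out)
        with pysam.VariantFile(str(out)) as vf:
            records = list(vf)
        assert len(records) == len(report.survivors)
        flagged = [r for r in records if "FLAGS" in r.info]
        assert len(flagged) == 1


class TestReportBookkeeping:
    def test_inconsistent_chaining_detected(self):
        report = FilterReport(
            stages=[FilterStage("a", 10, 5), FilterStage("b", 6, 2)],
            survivors=[],
        )
        with pytest.raises(AssertionError, match="chaining"):
            report.check_consistent()

    def test_report_tsv(self, tmp_path):
        report = FilterReport(
            stages=[FilterStage("a", 10, 5), FilterStage("b", 5, 2)],
            survivors=[rec(), rec(pos=15_000_001)],
        )
        report.check_consistent()
        path = tmp_path / "report.tsv"
        report.to_tsv(path)
        assert path.read_text().splitlines()[1] == "a\t10\t5"
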