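"""Candidate-region rare-variant filter cascade over a VCF.

The cascade mirrors a standard recessive-discovery workflow: restrict calls
to the shared autozygous regions (caller-PASS records only), remove known
polymorphisms (presence in an early dbSNP build, or minor allele frequency
>= 1% in a later build), keep only potentially protein-altering classes
(nonsynonymous SNVs, exonic indels, splice-consensus variants), and flag —
but do not remove — indels that sit inside a simple tandem repeat, a common
source of spurious "novel" calls. Annotations arrive on the VCF as INFO
keys ``DB129`` (flag), ``AF137`` (float) and ``FCLASS`` (string); no live
database lookup is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .gene_model import GenomeSequence, SequenceError
from .roh_mapping import RohRegion

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = {
    "nonsynonymous",
    "synonymous",
    "exonic_indel",
    "splice_consensus",
    "intronic",
    "intergenic",
    "other",
}
RETAINED_CLASSES = {"nonsynonymous", "exonic_indel", "splice_consensus"}
MAF_THRESHOLD = 0.01  # inclusive: records at exactly 1% are dropped
REPEAT_FLAG = "LIKELY_REPEAT_POLYMORPHISM"


@dataclass
class VariantRecord:
    """One biallelic VCF record with the cascade's annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    pass_flag: bool
    in_dbsnp129: bool = False
    maf_dbsnp137: float | None = None
    functional_class: str = "other"
    genotypes: dict[str, str] = field(default_factory=dict)
    raw: str | None = None  # original VCF line, for pass-through output
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.maf_dbsnp137 is not None and not 0.0 <= self.maf_dbsnp137 <= 1.0:
            raise ValueError(f"MAF {self.maf_dbsnp137} outside [0, 1]")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    """Per-stage bookkeeping plus the surviving records."""

    stages: list[FilterStage]
    survivors: list[VariantRecord]
    n_skipped_malformed: int = 0

    def check_consistent(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise AssertionError(
                    f"stage chaining broken: {prev.name} out={prev.n_out} but "
                    f"{nxt.name} in={nxt.n_in}"
                )
        for st in self.stages:
            if st.n_out > st.n_in:
                raise AssertionError(f"stage {st.name} grew the record set")
        if self.stages and len(self.survivors) != self.stages[-1].n_out:
            raise AssertionError("survivor count disagrees with final stage")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tn_in\tn_out"]
        lines += [f"{s.name}\t{s.n_in}\t{s.n_out}" for s in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> str:
        parts = [f"{s.name}: {s.n_in} -> {s.n_out}" for s in self.stages]
        return "; ".join(parts)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], str]:
    """Read a VCF into VariantRecords; returns (records, header text).

    Records that cannot be interpreted are skipped with a logged warning
    and counted on the returned list's ``skipped`` attribute stand-in (the
    caller receives the count via :func:`run_cascade`).
    """
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        header_text = str(vf.header)
        for rec in vf:
            try:
                alt = rec.alts[0] if rec.alts else "."
                maf = rec.info.get("AF137")
                if isinstance(maf, tuple):
                    maf = maf[0]
                fclass = rec.info.get("FCLASS", "other")
                if isinstance(fclass, tuple):
                    fclass = fclass[0]
                genotypes = {}
                for sample in rec.samples:
                    gt = rec.samples[sample].get("GT")
                    genotypes[sample] = (
                        "/".join("." if a is None else str(a) for a in gt)
                        if gt
                        else "./."
                    )
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        pass_flag=(
                            len(rec.filter) == 0 or "PASS" in list(rec.filter)
                        ),
                        in_dbsnp129=bool(rec.info.get("DB129", False)),
                        maf_dbsnp137=float(maf) if maf is not None else None,
                        functional_class=str(fclass),
                        genotypes=genotypes,
                        raw=str(rec).rstrip("\n"),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping malformed VCF record: %s", exc)
    read_vcf.last_skipped = skipped  # type: ignore[attr-defined]
    return records, header_text


def _merge_regions(regions: list[RohRegion]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        res = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= res[-1][1] + 1:
                res[-1][1] = max(res[-1][1], e)
            else:
                res.append([s, e])
        merged[chrom] = [(s, e) for s, e in res]
    return merged


def restrict_to_regions(
    variants: list[VariantRecord], regions: list[RohRegion]
) -> list[VariantRecord]:
    """Keep caller-PASS records whose position falls inside any region
    (inclusive bounds); overlapping regions are merged first."""
    merged = _merge_regions(regions)
    out = []
    for v in variants:
        if not v.pass_flag:
            continue
        for s, e in merged.get(v.chrom, ()):
            if s <= v.pos <= e:
                out.append(v)
                break
    return out


def filter_known(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Drop known polymorphisms: presence in the early dbSNP build, or MAF
    >= 1% in the later build. Unknown MAF is treated as not-common."""
    return [
        v
        for v in variants
        if not v.in_dbsnp129
        and (v.maf_dbsnp137 is None or v.maf_dbsnp137 < MAF_THRESHOLD)
    ]


def filter_functional(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep nonsynonymous SNVs, exonic indels and splice-consensus variants."""
    return [v for v in variants if v.functional_class in RETAINED_CLASSES]


def flag_repeat_context(
    v: VariantRecord,
    genome: GenomeSequence,
    unit_max: int = 6,
    min_copies: int = 4,
) -> bool | None:
    """True if an indel's inserted/deleted sequence is a whole multiple of a
    short tandem-repeat unit present at the site.

    Such indels are typical repeat-number polymorphisms. Returns None for a
    SNV (not applicable). The flagged record is annotated, never removed.
    """
    if not v.is_indel:
        return None
    if len(v.alt) > len(v.ref):
        changed = v.alt[len(v.ref) :] if v.alt.startswith(v.ref) else v.alt[1:]
    else:
        changed = v.ref[len(v.alt) :] if v.ref.startswith(v.alt) else v.ref[1:]
    if not changed:
        return False
    for u in range(1, min(unit_max, len(changed)) + 1):
        if len(changed) % u != 0:
            continue
        unit = changed[:u]
        if unit * (len(changed) // u) != changed:
            continue
        if _tandem_copies_at(genome, v.chrom, v.pos, unit) >= min_copies:
            return True
    return False


def _tandem_copies_at(
    genome: GenomeSequence, chrom: str, pos: int, unit: str
) -> int:
    """Longest run of consecutive ``unit`` copies in the reference tract
    adjacent to the anchor base at ``pos`` (copies counted rightward from
    pos+1 plus leftward ending at pos)."""
    u = len(unit)
    copies = 0
    p = pos + 1
    while p + u - 1 <= genome.end(chrom) and genome.fetch(chrom, p, p + u - 1) == unit:
        copies += 1
        p += u
    p = pos - u + 1
    while p >= genome.start(chrom) and genome.fetch(chrom, p, p + u - 1) == unit:
        copies += 1
        p -= u
    return copies


def run_cascade(
    vcf_path: str | Path,
    regions: list[RohRegion],
    genome: GenomeSequence | None = None,
    unit_max: int = 6,
    min_copies: int = 4,
) -> FilterReport:
    """Apply the full cascade and report per-stage counts.

    Stage order: region restriction (PASS only) -> known-polymorphism
    removal -> functional-class filter -> tandem-repeat flagging of
    surviving indels (annotation only).
    """
    variants, _header = read_vcf(vcf_path)
    skipped = getattr(read_vcf, "last_skipped", 0)
    stages: list[FilterStage] = []

    in_region = restrict_to_regions(variants, regions)
    stages.append(FilterStage("restrict_to_regions", len(variants), len(in_region)))

    rare = filter_known(in_region)
    stages.append(FilterStage("filter_known", len(in_region), len(rare)))

    functional = filter_functional(rare)
    stages.append(FilterStage("filter_functional", len(rare), len(functional)))

    if genome is not None:
        for v in functional:
            try:
                if flag_repeat_context(v, genome, unit_max, min_copies):
                    v.flags.append(REPEAT_FLAG)
            except SequenceError:
                logger.warning(
                    "no reference context for %s:%d; repeat flag skipped",
                    v.chrom,
                    v.pos,
                )
    stages.append(FilterStage("flag_repeat_context", len(functional), len(functional)))

    report = FilterReport(
        stages=stages, survivors=functional, n_skipped_malformed=skipped
    )
    report.check_consistent()
    return report


def write_survivors_vcf(
    report: FilterReport, header_text: str, path: str | Path
) -> None:
    """Write surviving records back out as VCF (input header passed through)."""
    flag_line = (
        '##INFO=<ID=FLAGS,Number=.,Type=String,'
        'Description="Cascade annotation flags">\n'
    )
    if "ID=FLAGS" not in header_text:
        header_text = header_text.replace("#CHROM", flag_line + "#CHROM", 1)
    with open(path, "w") as fh:
        fh.write(header_text)
        for v in report.survivors:
            line = v.raw or ""
            if v.flags and line:
                fields = line.split("\t")
                extra = "FLAGS=" + ",".join(v.flags)
                fields[7] = extra if fields[7] == "." else fields[7] + ";" + extra
                line = "\t".join(fields)
            fh.write(line + "\n")
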