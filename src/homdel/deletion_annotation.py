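"""HGVS deletion parsing, consequence annotation and in-silico PCR.

A genomic deletion described in coding-DNA coordinates (e.g.
``c.294+139_531+478del``) is resolved against a :class:`TranscriptModel`
into its genomic span, the split into coding and intronic bases, its
reading-frame status and — for codon-aligned in-frame deletions — the
``p.`` protein consequence. The diagnostic PCR of such a deletion is
reproduced positionally: amplicon lengths on reference and deleted alleles,
and a genotype call from the two assays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio.SeqUtils import seq3

from .gene_model import (
    CdsCoordinate,
    CoordinateError,
    GenomeSequence,
    TranscriptModel,
    translate_cds,
)


class HgvsParseError(ValueError):
    """The HGVS string does not match the supported deletion grammar."""


class AssayFailureError(RuntimeError):
    """Neither PCR assay produced a product for an allele (no-template signal)."""


_HGVS_DEL_RE = re.compile(
    r"c\.(\d+)(?:\s*([+-])\s*(\d+))?_(\d+)(?:\s*([+-])\s*(\d+))?del"
)


@dataclass(frozen=True)
class DeletionDescription:
    """A deletion in c. coordinates, endpoints inclusive, start <= end in
    transcription order."""

    start: CdsCoordinate
    end: CdsCoordinate
    raw: str | None = None


@dataclass
class DeletionConsequence:
    """Full annotation of one genomic deletion against a transcript."""

    chrom: str
    genomic_start: int
    genomic_end: int
    total_length: int
    coding_bases_removed: int
    intronic_bases_removed: int
    in_frame: bool
    hgvs_c: str
    protein_hgvs: str | None = None
    first_residue: int | None = None
    last_residue: int | None = None
    first_residue_aa: str | None = None
    last_residue_aa: str | None = None
    wt_protein_length: int | None = None
    mut_protein_length: int | None = None
    frameshift: bool = False
    junction: bool = False
    unsupported: str | None = None


def parse_hgvs_c_del(s: str, model: TranscriptModel) -> DeletionDescription:
    """Parse ``c.<pos>_<pos>del`` (optional ±intronic offsets; whitespace
    tolerated around the sign, as journals sometimes typeset it)."""
    m = _HGVS_DEL_RE.fullmatch(s.strip())
    if m is None:
        raise HgvsParseError(f"not a supported HGVS c. deletion: {s!r}")

    def _coord(base, sign, off) -> CdsCoordinate:
        offset = 0
        if sign:
            offset = int(off) * (1 if sign == "+" else -1)
        return CdsCoordinate(int(base), offset)

    start = _coord(m.group(1), m.group(2), m.group(3))
    end = _coord(m.group(4), m.group(5), m.group(6))
    g1 = model.cds_to_genomic(start)  # validates against the model
    g2 = model.cds_to_genomic(end)
    step = 1 if model.strand == "+" else -1
    if (g2 - g1) * step < 0:
        raise HgvsParseError(
            f"deletion endpoints reversed in transcription order: {s!r}"
        )
    return DeletionDescription(start=start, end=end, raw=s)


def format_hgvs_c_del(d: DeletionDescription) -> str:
    """Canonical (whitespace-free) HGVS form."""
    return f"c.{d.start}_{d.end}del"


def annotate_deletion(
    d: DeletionDescription,
    model: TranscriptModel,
    genome: GenomeSequence,
    normalize_3prime: bool = False,
) -> DeletionConsequence:
    """Compute the genomic span, coding/intronic split, frame status and
    protein consequence of a deletion.

    ``normalize_3prime`` optionally shifts the deletion to its most-3'
    equivalent position before annotating (HGVS normalization); default off,
    matching breakpoints reported directly from sequencing.
    """
    g1 = model.cds_to_genomic(d.start)
    g2 = model.cds_to_genomic(d.end)
    gstart, gend = min(g1, g2), max(g1, g2)

    if normalize_3prime:
        step = 1 if model.strand == "+" else -1
        while True:
            if step == 1:
                nxt, first = gend + 1, gstart
                if nxt > genome.end(model.chrom):
                    break
                if genome.base(model.chrom, nxt) != genome.base(model.chrom, first):
                    break
                gstart += 1
                gend += 1
            else:
                nxt, last = gstart - 1, gend
                if nxt < genome.start(model.chrom):
                    break
                if genome.base(model.chrom, nxt) != genome.base(model.chrom, last):
                    break
                gstart -= 1
                gend -= 1

    total = gend - gstart + 1
    removed_c = model.coding_c_positions_in(gstart, gend)
    coding = len(removed_c)
    # exonic-but-UTR bases in the span would make coding+intronic != total
    exonic_total = sum(
        max(0, min(e, gend) - max(s, gstart) + 1) for s, e in model.exons
    )
    cons = DeletionConsequence(
        chrom=model.chrom,
        genomic_start=gstart,
        genomic_end=gend,
        total_length=total,
        coding_bases_removed=coding,
        intronic_bases_removed=total - exonic_total,
        in_frame=coding % 3 == 0,
        hgvs_c=format_hgvs_c_del(d),
    )
    if exonic_total != coding:
        cons.unsupported = "deletion removes non-coding (UTR) exonic bases"
        return cons
    if coding == 0:
        return cons

    c_lo, c_hi = removed_c[0], removed_c[-1]
    if removed_c != list(range(c_lo, c_hi + 1)):
        cons.unsupported = "removed coding bases are not a contiguous CDS run"
        return cons
    if c_lo <= 3:
        cons.unsupported = "deletion removes the initiator codon"
        return cons
    if c_hi > model.cds_length - 3:
        cons.unsupported = "deletion removes the terminator codon"
        return cons

    wt_protein = translate_cds(model.cds_sequence(genome))
    cons.wt_protein_length = len(wt_protein)
    if not cons.in_frame:
        cons.frameshift = True
        cons.protein_hgvs = "fs"
        return cons

    n_codons = coding // 3
    cons.mut_protein_length = len(wt_protein) - n_codons
    if c_lo % 3 == 1 and c_hi % 3 == 0:
        r1, r2 = (c_lo + 2) // 3, c_hi // 3
        aa1, aa2 = seq3(wt_protein[r1 - 1]), seq3(wt_protein[r2 - 1])
        cons.first_residue, cons.last_residue = r1, r2
        cons.first_residue_aa, cons.last_residue_aa = aa1, aa2
        if r1 == r2:
            cons.protein_hgvs = f"p.{aa1}{r1}del"
        else:
            cons.protein_hgvs = f"p.{aa1}{r1}_{aa2}{r2}del"
    else:
        # in-frame but not codon-aligned: a novel junction residue is created
        cons.junction = True
    return cons


# -- in-silico PCR ----------------------------------------------------------


@dataclass(frozen=True)
class PrimerPair:
    """Primer footprints on the reference (1-based inclusive intervals);
    forward entirely 5' of reverse, each 15-35 nt."""

    chrom: str
    forward: tuple[int, int]
    reverse: tuple[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        for name, (s, e) in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= e - s + 1 <= 35:
                raise ValueError(f"{name} primer length {e - s + 1} outside 15-35 nt")
        if self.forward[1] >= self.reverse[0]:
            raise ValueError("forward primer must lie entirely 5' of reverse primer")


def in_silico_pcr(template, primers: PrimerPair) -> int | None:
    """Amplicon length on a template (reference genome or mutant allele).

    Purely positional: primers are assumed to match perfectly where their
    reference footprint survives on the template. Returns the product
    length in bp, or ``None`` for no product (a footprint destroyed, e.g.
    by a deletion breakpoint under it).
    """
    fs, fe = primers.forward
    rs, re_ = primers.reverse
    if hasattr(template, "lift"):  # mutant allele with coordinate lift
        for s, e in ((fs, fe), (rs, re_)):
            if not template.contains_interval(primers.chrom, s, e):
                return None
        return template.lift(primers.chrom, re_) - template.lift(primers.chrom, fs) + 1
    if not (
        template.start(primers.chrom) <= fs and re_ <= template.end(primers.chrom)
    ):
        return None
    return re_ - fs + 1


def classify_pcr_genotype(
    exon6_products: list[int | None],
    longrange_products: list[int | None],
) -> str:
    """Combine the exon-internal and long-range assays per allele into a
    genotype: ``wild_type`` / ``carrier`` / ``homozygous_deleted``.

    An allele with a product in the exon-internal assay is intact; one with
    no exon product but a (shortened) long-range product carries the
    deletion. An allele yielding no product in either assay signals assay
    failure (the positive-control logic of a diagnostic gel).
    """
    if len(exon6_products) != len(longrange_products):
        raise ValueError("assay result lists must cover the same alleles")
    n_del = 0
    for e6, lr in zip(exon6_products, longrange_products):
        if e6 is not None:
            continue
        if lr is None:
            raise AssayFailureError(
                "no product in either assay for an allele: assay failure"
            )
        n_del += 1
    if n_del == 0:
        return "wild_type"
    if n_del == len(exon6_products):
        return "homozygous_deleted"
    return "carrier"


# -- report output ----------------------------------------------------------

_TSV_FIELDS = [
    "chrom",
    "genomic_start",
    "genomic_end",
    "total_length",
    "coding_bases_removed",
    "intronic_bases_removed",
    "in_frame",
    "hgvs_c",
    "protein_hgvs",
    "first_residue",
    "last_residue",
    "wt_protein_length",
    "mut_protein_length",
    "frameshift",
    "junction",
    "unsupported",
]


def write_consequence_tsv(cons: DeletionConsequence, path: str | Path) -> None:
    values = [str(getattr(cons, f)) for f in _TSV_FIELDS]
    Path(path).write_text("\t".join(_TSV_FIELDS) + "\n" + "\t".join(values) + "\n")


def write_consequence_vcf(
    cons: DeletionConsequence,
    genome: GenomeSequence,
    path: str | Path,
    contig_length: int | None = None,
) -> None:
    """Emit the deletion as a VCF v4.2 symbolic record (SVTYPE=DEL)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length difference '
        'between ALT and REF alleles">'
    )
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    length = contig_length or genome.end(cons.chrom)
    header.contigs.add(cons.chrom, length=length)
    anchor = cons.genomic_start - 1
    ref = genome.base(cons.chrom, anchor)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        rec = out.new_record(
            contig=cons.chrom,
            start=anchor - 1,  # 0-based
            alleles=(ref, "<DEL>"),
            id=cons.hgvs_c,
        )
        rec.stop = cons.genomic_end
        rec.info["SVTYPE"] = "DEL"
        rec.info["SVLEN"] = -cons.total_length
        out.write(rec)
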