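"""Synthetic inputs with ground truth for the whole discovery pipeline.

Everything the pipeline consumes can be generated here, deterministically
from a seed: a toy genome hosting a 7-exon gene whose coordinate
arithmetic matches the worked examples used throughout the package
(canonical model), pedigree SNP genotypes with planted autozygous
segments, per-base exon depth tracks with a planted homozygous deletion,
and an annotated VCF whose filter-cascade behaviour is known by
construction. Each generator returns (or records in a TruthSet) exactly
what it planted, so detectors can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import GenomeSequence, TranscriptModel
from .roh_mapping import GenotypeMatrix

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}

# --- canonical toy gene geometry -------------------------------------------
# 7 plus-strand exons; CDS 1344 nt = 447 codons + stop; per-exon CDS spans
# 60/60/60/60/54/237/813. Intron 5 (1770 bp) and intron 6 (1000 bp) are
# sized so that a deletion c.294+139_531+478 spans exactly 2347 bp: 1632 bp
# of intron 5 + all 237 bp of exon 6 + 478 bp of intron 6. These intron
# lengths are synthetic bookkeeping, not measurements of any real gene.
CANONICAL_CHROM = "chrG"
CANONICAL_CHROM_LENGTH = 1_100_000
CANONICAL_EXONS = [
    (1_000_001, 1_000_110),  # 50 bp 5' UTR + 60 bp CDS
    (1_000_611, 1_000_670),
    (1_001_171, 1_001_230),
    (1_001_731, 1_001_790),
    (1_002_291, 1_002_344),  # 54 bp; last coding base is c.294
    (1_004_115, 1_004_351),  # 237 bp; c.295-531
    (1_005_352, 1_006_214),  # 813 bp CDS (incl. stop) + 50 bp 3' UTR
]
CANONICAL_CDS_START = 1_000_051
CANONICAL_CDS_END = 1_006_164
CANONICAL_DELETION = (1_002_483, 1_004_829)  # c.294+139 .. c.531+478
CANONICAL_HGVS = "c.294+139_531+478del"


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "U"
    affected: bool = False


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = {i.id for i in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        by_id = {i.id: i for i in self.individuals}
        for ind in self.individuals:
            seen = set()
            stack = [p for p in (ind.father, ind.mother) if p]
            while stack:
                cur = stack.pop()
                if cur == ind.id:
                    raise ValueError(f"{ind.id} is its own ancestor")
                if cur in seen or cur not in by_id:
                    continue
                seen.add(cur)
                parent = by_id[cur]
                stack.extend(p for p in (parent.father, parent.mother) if p)

    @property
    def samples(self) -> list[str]:
        return [i.id for i in self.individuals]

    @property
    def affected(self) -> list[str]:
        return [i.id for i in self.individuals if i.affected]


def default_pedigree() -> Pedigree:
    """A consanguineous nuclear family: 2 parents, 6 children, 3 affected."""
    return Pedigree(
        [
            Individual("V_1", sex="M"),
            Individual("V_2", sex="F"),
            Individual("VI_1", "V_1", "V_2"),
            Individual("VI_2", "V_1", "V_2", affected=True),
            Individual("VI_3", "V_1", "V_2", affected=True),
            Individual("VI_4", "V_1", "V_2", affected=True),
            Individual("VI_5", "V_1", "V_2"),
            Individual("VI_6", "V_1", "V_2"),
        ]
    )


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int


# Two shared autozygous segments with the bounds the ROH stage should
# recover, plus one private (single-sample) ROH per affected individual.
DEFAULT_SHARED_SEGMENTS = [
    Segment("chr1", 11_698_902, 26_171_473),
    Segment("chr4", 71_230_491, 83_403_217),
]
DEFAULT_PRIVATE_SEGMENTS = {
    "VI_2": Segment("chr1", 1_000_000, 4_000_000),
    "VI_3": Segment("chr1", 5_500_000, 8_500_000),
    "VI_4": Segment("chr4", 66_000_000, 69_500_000),
}
DEFAULT_CHROM_RANGES = {
    "chr1": (5_000, 30_000_000),
    "chr4": (65_000_000, 95_000_000),
}


@dataclass
class TruthSet:
    """Everything the generators planted, queryable by tests."""

    shared_segments: list[Segment] = field(default_factory=list)
    private_segments: dict[str, Segment] = field(default_factory=dict)
    deletion_interval: tuple[int, int] | None = None
    deletion_chrom: str | None = None
    deletion_hgvs: str | None = None
    deleted_exons: list[int] = field(default_factory=list)
    variant_truth: list[dict] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        d["shared_segments"] = [Segment(**s) for s in d["shared_segments"]]
        d["private_segments"] = {
            k: Segment(**s) for k, s in d["private_segments"].items()
        }
        if d.get("deletion_interval"):
            d["deletion_interval"] = tuple(d["deletion_interval"])
        return cls(**d)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons_with_stop: int) -> str:
    """A stop-free CDS ending in TAA, with codon 99 = TAT (Tyr) and codon
    177 = GAA (Glu) pinned for the worked protein examples."""
    codons = []
    for i in range(1, n_codons_with_stop + 1):
        if i == 1:
            codons.append("ATG")
        elif i == 99:
            codons.append("TAT")
        elif i == 177:
            codons.append("GAA")
        elif i == n_codons_with_stop:
            codons.append("TAA")
        else:
            while True:
                cod = _random_bases(rng, 3)
                if cod not in _STOPS:
                    break
            codons.append(cod)
    return "".join(codons)


def make_canonical_model(
    seed: int = 0, outdir: str | Path | None = None
) -> tuple[GenomeSequence, TranscriptModel, dict[str, Path]]:
    """Build the canonical toy genome and transcript model.

    Deterministic in ``seed``. If ``outdir`` is given, FASTA, GFF3 and TSV
    model files are written there and their paths returned.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, CANONICAL_CHROM_LENGTH))

    model = TranscriptModel(
        chrom=CANONICAL_CHROM,
        strand="+",
        exons=CANONICAL_EXONS,
        cds_start=CANONICAL_CDS_START,
        cds_end=CANONICAL_CDS_END,
        gene_id="TOYGENE",
        transcript_id="TOYTX1",
    )
    cds = _random_cds(rng, model.cds_length // 3)
    k = 0
    for s, e in model.exons:
        lo, hi = max(s, model.cds_start), min(e, model.cds_end)
        if lo <= hi:
            n = hi - lo + 1
            seq[lo - 1 : hi - 1 + 1] = list(cds[k : k + n])
            k += n

    # Pin the deletion-breakpoint context so that HGVS 3' (or 5')
    # normalization cannot shift the planted deletion: the base entering the
    # span from either side differs from the base it would replace.
    ds, de = CANONICAL_DELETION
    for window_start, window in (
        (1_002_473, "TGCATCGATG" + "ATCGGATCCA"),
        (1_004_820, "CAGGTACGAT" + "CGATTCAGGC"),
    ):
        seq[window_start - 1 : window_start - 1 + len(window)] = list(window)
    assert seq[ds - 1] != seq[de], "3'-shift guard"
    assert seq[ds - 2] != seq[de - 1], "5'-shift guard"

    genome = GenomeSequence({CANONICAL_CHROM: "".join(seq)})
    model.check_sequence(genome)

    paths: dict[str, Path] = {}
    if outdir is not None:
        from .gene_model import write_transcript_gff3, write_transcript_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["fasta"] = outdir / "genome.fasta"
        genome.to_fasta(paths["fasta"])
        paths["gff3"] = outdir / "model.gff3"
        write_transcript_gff3(model, paths["gff3"])
        paths["tsv"] = outdir / "model.tsv"
        write_transcript_tsv(model, paths["tsv"])
    return genome, model, paths


# --- mutant allele ----------------------------------------------------------


@dataclass
class MutantAllele:
    """A haploid allele carrying one deletion, with a coordinate lift from
    reference to mutant coordinates."""

    genome: GenomeSequence
    chrom: str
    del_start: int
    del_end: int

    def __post_init__(self) -> None:
        if self.chrom not in self.genome:
            raise ValueError(f"unknown sequence {self.chrom!r}")
        if not (
            self.genome.start(self.chrom)
            <= self.del_start
            <= self.del_end
            <= self.genome.end(self.chrom)
        ):
            raise ValueError("deletion interval outside the sequence")

    @property
    def deleted_length(self) -> int:
        return self.del_end - self.del_start + 1

    def lift(self, chrom: str, pos: int) -> int | None:
        """Map a reference position onto the mutant allele (None if deleted)."""
        if chrom != self.chrom:
            return pos
        if pos < self.del_start:
            return pos
        if pos > self.del_end:
            return pos - self.deleted_length
        return None

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if the whole reference interval survives on this allele."""
        if chrom != self.chrom:
            return chrom in self.genome
        if not (self.genome.start(chrom) <= start and end <= self.genome.end(chrom)):
            return False
        return end < self.del_start or start > self.del_end

    def sequence(self, chrom: str) -> str:
        full = self.genome.fetch(
            chrom, self.genome.start(chrom), self.genome.end(chrom)
        )
        if chrom != self.chrom:
            return full
        off = self.genome.start(chrom)
        return full[: self.del_start - off] + full[self.del_end - off + 1 :]


def apply_deletion(
    genome: GenomeSequence, chrom: str, start: int, end: int
) -> MutantAllele:
    """Remove ``chrom:start-end`` (1-based inclusive) from an allele."""
    return MutantAllele(genome=genome, chrom=chrom, del_start=start, del_end=end)


# --- pedigree genotypes -----------------------------------------------------


def simulate_pedigree_genotypes(
    ped: Pedigree | None = None,
    shared_segments: list[Segment] | None = None,
    private_segments: dict[str, Segment] | None = None,
    chrom_ranges: dict[str, tuple[int, int]] | None = None,
    marker_spacing_bp: int = 5_000,
    het_rate: float = 0.35,
    error_rate: float = 0.002,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthSet]:
    """SNP genotypes for the family with planted autozygosity.

    Inside a planted segment every carrier-of-two-copies sample is
    homozygous, with all affected individuals sharing the segment and each
    optionally owning one private segment; elsewhere calls are drawn with
    ``het_rate`` heterozygosity. Genotyping error is modeled as an
    allele-swap miscall at ``error_rate`` (AA<->BB; a miscalled AB becomes
    a random homozygote), so an autozygous tract stays a homozygous run —
    call-level het/missing tolerance of the detector is exercised by
    dedicated tests with explicit matrices.
    """
    ped = ped or default_pedigree()
    shared = (
        shared_segments if shared_segments is not None else DEFAULT_SHARED_SEGMENTS
    )
    private = (
        private_segments
        if private_segments is not None
        else {k: v for k, v in DEFAULT_PRIVATE_SEGMENTS.items() if k in ped.affected}
    )
    ranges = chrom_ranges or DEFAULT_CHROM_RANGES
    for seg in list(shared) + list(private.values()):
        if seg.chrom not in ranges:
            raise ValueError(f"segment chromosome {seg.chrom!r} not simulated")
        lo, hi = ranges[seg.chrom]
        if seg.start < lo or seg.end > hi:
            raise ValueError(f"segment {seg} outside simulated range {lo}-{hi}")

    rng = np.random.default_rng(seed)
    samples = ped.samples
    affected = set(ped.affected)

    marker_rows = []
    call_blocks = []
    for chrom, (lo, hi) in ranges.items():
        pos = np.arange(lo, hi + 1, marker_spacing_bp)
        n = len(pos)
        marker_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "id": [f"{chrom}_m{i}" for i in range(n)],
                }
            )
        )
        # shared-segment allele per marker, identical across affecteds
        seg_allele = rng.choice(["AA", "BB"], size=n)
        block = {}
        for sample in samples:
            is_het = rng.random(n) < het_rate
            hom_choice = rng.choice(["AA", "BB"], size=n)
            calls = np.where(is_het, "AB", hom_choice)
            if sample in affected:
                for seg in shared:
                    if seg.chrom == chrom:
                        mask = (pos >= seg.start) & (pos <= seg.end)
                        calls = np.where(mask, seg_allele, calls)
            pseg = private.get(sample)
            if pseg is not None and pseg.chrom == chrom:
                mask = (pos >= pseg.start) & (pos <= pseg.end)
                calls = np.where(mask, rng.choice(["AA", "BB"]), calls)
            if error_rate > 0:
                err = rng.random(n) < error_rate
                swap = np.where(
                    calls == "AA",
                    "BB",
                    np.where(calls == "BB", "AA", rng.choice(["AA", "BB"], size=n)),
                )
                calls = np.where(err, swap, calls)
            block[sample] = calls
        call_blocks.append(pd.DataFrame(block))

    matrix = GenotypeMatrix(
        pd.concat(marker_rows, ignore_index=True),
        pd.concat(call_blocks, ignore_index=True),
    )
    truth = TruthSet(
        shared_segments=list(shared),
        private_segments=dict(private),
        seeds={"genotypes": seed},
    )
    return matrix, truth


# --- exon depth -------------------------------------------------------------


def simulate_exon_depths(
    model: TranscriptModel,
    copy_number_by_exon: dict[int, int] | None = None,
    mean_depth: float = 230.0,
    seed: int = 0,
    noise_rate: float = 0.0024,
) -> pd.DataFrame:
    """Per-base Poisson depth over a transcript's exons for one sample.

    Depth at each exon base is Poisson with mean ``mean_depth * cn / 2``
    for exon copy number ``cn``; fully deleted exons (cn 0) instead receive
    sparse mis-mapping noise, Poisson with mean ``noise_rate * mean_depth``
    — so a homozygously deleted exon shows near-zero, not exactly zero,
    coverage. Returns a per-base track (chrom, pos, depth).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    cn_map = copy_number_by_exon or {}
    n_exons = len(model.exons)
    for idx in cn_map:
        if not 1 <= idx <= n_exons:
            raise ValueError(f"unknown exon index {idx}")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (s, e) in enumerate(model.exons, start=1):
        cn = cn_map.get(i, 2)
        lam = mean_depth * cn / 2 if cn > 0 else mean_depth * noise_rate
        depth = rng.poisson(lam, size=e - s + 1)
        rows.append(
            pd.DataFrame(
                {"chrom": model.chrom, "pos": np.arange(s, e + 1), "depth": depth}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_depth_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


# --- annotated VCF ----------------------------------------------------------


@dataclass
class VcfComposition:
    """Record counts by truth category.

    Defaults produce 672 caller-PASS in-region records of which 46 survive
    the known-polymorphism filter and exactly 1 (a tandem-repeat-context
    insertion) survives the functional filter, plus region/filter rejects.
    """

    n_known_common: int = 626
    n_rare_silent: int = 45
    n_rare_functional: int = 0
    n_repeat_insertion: int = 1
    n_nonpass: int = 25
    n_outside: int = 30

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


REPEAT_INSERTION_POS = 17_026_040  # anchor; a (CGG)8 tract starts at pos+1
REPEAT_UNIT = "CGG"
_SILENT_CLASSES = ["synonymous", "intronic", "intergenic", "other"]
_ALL_CLASSES = _SILENT_CLASSES + ["nonsynonymous"]


def simulate_vcf(
    regions,
    out_vcf: str | Path,
    composition: VcfComposition | None = None,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    samples: list[str] | None = None,
    margin: int = 2_000_000,
) -> tuple[Path, TruthSet, GenomeSequence]:
    """Write an annotated VCF over candidate regions, with known truth.

    ``regions`` is a list of objects with chrom/start/end (RohRegion or
    Segment). If no genome is given, a synthetic reference window covering
    each region (plus ``margin``) is generated; a (CGG)n tract is embedded
    at the planted repeat-insertion site. Returns the VCF path, the truth
    set, and the genome used.
    """
    import pysam

    comp = composition or VcfComposition()
    rng = np.random.default_rng(seed)
    samples = samples or default_pedigree().samples
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one candidate region")

    if genome is None:
        seqs, starts = {}, {}
        for chrom in {r.chrom for r in regions}:
            lo = min(r.start for r in regions if r.chrom == chrom) - margin
            hi = max(r.end for r in regions if r.chrom == chrom) + margin
            lo = max(1, lo)
            seqs[chrom] = _random_bases(rng, hi - lo + 1)
            starts[chrom] = lo
        genome = GenomeSequence(seqs, starts)

    # choose the repeat-insertion site and embed its reference tract
    repeat_records = []
    if comp.n_repeat_insertion > 0:
        host = next(
            (r for r in regions if r.start <= REPEAT_INSERTION_POS <= r.end), None
        )
        anchor = REPEAT_INSERTION_POS if host else regions[0].start + 10_000
        host = host or regions[0]
        tract = REPEAT_UNIT * 8
        chrom = host.chrom
        off = genome.start(chrom)
        seq = list(genome.fetch(chrom, genome.start(chrom), genome.end(chrom)))
        seq[anchor - off + 1 : anchor - off + 1 + len(tract)] = list(tract)
        genome = GenomeSequence(
            {**{c: genome.sequence(c) for c in genome.names() if c != chrom},
             chrom: "".join(seq)},
            {c: genome.start(c) for c in genome.names()},
        )
        for _ in range(comp.n_repeat_insertion):
            repeat_records.append((chrom, anchor))

    spans = [(r.chrom, r.start, r.end) for r in regions]
    total_span = sum(e - s + 1 for _, s, e in spans)
    n_inside = comp.n_known_common + comp.n_rare_silent + comp.n_rare_functional
    if n_inside + comp.n_nonpass > total_span // 100:
        raise ValueError("composition exceeds available positions")

    weights = np.array([e - s + 1 for _, s, e in spans], dtype=float)
    weights /= weights.sum()
    reserved = {(c, p) for c, p in repeat_records}
    reserved |= {
        (c, p + d) for c, p in repeat_records for d in range(-30, 31)
    }

    def draw_positions(n, inside=True):
        out = []
        while len(out) < n:
            if inside:
                i = rng.choice(len(spans), p=weights)
                chrom, s, e = spans[i]
                pos = int(rng.integers(s, e + 1))
            else:
                # clearly outside: the outer half of the flanking margin, so
                # that detected-region boundary jitter cannot swallow them
                chrom, s, e = spans[int(rng.choice(len(spans)))]
                lo, hi = genome.start(chrom), genome.end(chrom)
                gap_lo = max(lo, s - margin)
                gap_hi = min(hi, e + margin)
                pos = (
                    int(rng.integers(gap_lo, (gap_lo + s) // 2))
                    if rng.random() < 0.5 and gap_lo < s
                    else int(rng.integers((e + gap_hi) // 2, gap_hi + 1))
                )
            if (chrom, pos) in reserved:
                continue
            in_any = any(
                c == chrom and s <= pos <= e for c, s, e in spans
            )
            if in_any != inside:
                continue
            reserved.add((chrom, pos))
            out.append((chrom, pos))
        return out

    truth_records = []

    def snv_alleles(chrom, pos):
        ref = genome.base(chrom, pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return ref, str(alt)

    for chrom, pos in draw_positions(comp.n_known_common):
        ref, alt = snv_alleles(chrom, pos)
        known_by_129 = bool(rng.random() < 0.5)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, category="known_common",
                pass_flag=True, db129=known_by_129,
                af137=float(np.round(rng.uniform(0.01, 0.5), 4))
                if not known_by_129 or rng.random() < 0.5
                else None,
                fclass=str(rng.choice(_ALL_CLASSES)),
            )
        )
    for chrom, pos in draw_positions(comp.n_rare_silent):
        ref, alt = snv_alleles(chrom, pos)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, category="rare_silent",
                pass_flag=True, db129=False,
                af137=float(np.round(rng.uniform(0.0, 0.0099), 4))
                if rng.random() < 0.5
                else None,
                fclass=str(rng.choice(_SILENT_CLASSES)),
            )
        )
    for chrom, pos in draw_positions(comp.n_rare_functional):
        ref, alt = snv_alleles(chrom, pos)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, category="rare_functional",
                pass_flag=True, db129=False, af137=None, fclass="nonsynonymous",
            )
        )
    for chrom, pos in repeat_records:
        ref = genome.base(chrom, pos)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=ref + REPEAT_UNIT * 5,
                category="repeat_insertion", pass_flag=True, db129=False,
                af137=None, fclass="exonic_indel",
            )
        )
    for chrom, pos in draw_positions(comp.n_nonpass):
        ref, alt = snv_alleles(chrom, pos)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, category="nonpass",
                pass_flag=False, db129=False, af137=None,
                fclass=str(rng.choice(_ALL_CLASSES)),
            )
        )
    for chrom, pos in draw_positions(comp.n_outside, inside=False):
        ref, alt = snv_alleles(chrom, pos)
        truth_records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, category="outside",
                pass_flag=True, db129=False, af137=None,
                fclass=str(rng.choice(_ALL_CLASSES)),
            )
        )

    truth_records.sort(key=lambda r: (r["chrom"], r["pos"]))

    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=LowQual,Description="Below caller thresholds">')
    header.add_line(
        '##INFO=<ID=DB129,Number=0,Type=Flag,Description="Present in the early '
        'dbSNP build">'
    )
    header.add_line(
        '##INFO=<ID=AF137,Number=1,Type=Float,Description="Minor allele frequency '
        'in the later dbSNP build">'
    )
    header.add_line(
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted({c for c, _, _ in spans}):
        header.contigs.add(chrom, length=genome.end(chrom) + 1_000_000)
    for s in samples:
        header.add_sample(s)

    affected = set(default_pedigree().affected) & set(samples)
    out_vcf = Path(out_vcf)
    with pysam.VariantFile(str(out_vcf), "w", header=header) as out:
        for r in truth_records:
            rec = out.new_record(
                contig=r["chrom"],
                start=r["pos"] - 1,
                alleles=(r["ref"], r["alt"]),
            )
            rec.filter.add("PASS" if r["pass_flag"] else "LowQual")
            if r["db129"]:
                rec.info["DB129"] = True
            if r["af137"] is not None:
                rec.info["AF137"] = r["af137"]
            rec.info["FCLASS"] = r["fclass"]
            rare = r["category"] in {"rare_functional", "repeat_insertion"}
            for s in samples:
                if rare:
                    gt = (1, 1) if s in affected else (0, 1)
                else:
                    gt = tuple(sorted(rng.integers(0, 2, size=2).tolist()))
                rec.samples[s]["GT"] = gt
            out.write(rec)

    truth = TruthSet(variant_truth=truth_records, seeds={"vcf": seed})
    return out_vcf, truth, genome


# --- complete fixture -------------------------------------------------------

# Panel per-sample mean depths; their mean (230) and spread mirror a
# five-exome control panel with unequal library sizes.
DEFAULT_PANEL_DEPTHS = (200.0, 210.0, 230.0, 250.0, 260.0)
DEFAULT_CASE_DEPTH = 230.0


def write_fixture(outdir: str | Path, seed: int = 0) -> dict:
    """Write a complete, self-consistent input set for the pipeline.

    Emits genome FASTA (toy gene chromosome plus candidate-region windows),
    gene model (GFF3 + TSV), pedigree genotype TSV, per-base depth tracks
    for the case and a 5-exome panel (case homozygously deleted for exon
    6), an annotated VCF, the truth JSON and a ready-to-run pipeline
    config. Deterministic in ``seed``. Returns a dict of paths plus the
    combined truth set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, model, _ = make_canonical_model(seed=seed)

    matrix, geno_truth = simulate_pedigree_genotypes(seed=seed + 1)
    genotypes_path = outdir / "genotypes.tsv"
    matrix.to_tsv(genotypes_path)

    vcf_path, vcf_truth, region_genome = simulate_vcf(
        DEFAULT_SHARED_SEGMENTS, outdir / "variants.vcf", seed=seed + 2
    )

    combined = GenomeSequence(
        {
            **{c: genome.sequence(c) for c in genome.names()},
            **{c: region_genome.sequence(c) for c in region_genome.names()},
        },
        {
            **{c: genome.start(c) for c in genome.names()},
            **{c: region_genome.start(c) for c in region_genome.names()},
        },
    )
    fasta_path = outdir / "genome.fasta"
    combined.to_fasta(fasta_path)
    from .gene_model import write_transcript_gff3, write_transcript_tsv

    model_path = outdir / "model.gff3"
    write_transcript_gff3(model, model_path)
    write_transcript_tsv(model, outdir / "model.tsv")

    deleted_exon = 6
    case_track = simulate_exon_depths(
        model,
        {deleted_exon: 0},
        mean_depth=DEFAULT_CASE_DEPTH,
        seed=seed + 3,
    )
    case_path = outdir / "depth_case.tsv"
    write_depth_tsv(case_track, case_path)
    panel_paths = []
    for i, depth in enumerate(DEFAULT_PANEL_DEPTHS, start=1):
        track = simulate_exon_depths(model, {}, mean_depth=depth, seed=seed + 10 + i)
        p = outdir / f"depth_panel{i}.tsv"
        write_depth_tsv(track, p)
        panel_paths.append(p)

    truth = TruthSet(
        shared_segments=geno_truth.shared_segments,
        private_segments=geno_truth.private_segments,
        deletion_interval=CANONICAL_DELETION,
        deletion_chrom=CANONICAL_CHROM,
        deletion_hgvs=CANONICAL_HGVS,
        deleted_exons=[deleted_exon],
        variant_truth=vcf_truth.variant_truth,
        seeds={"fixture": seed, **geno_truth.seeds, **vcf_truth.seeds},
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)

    config = {
        "genotypes": str(genotypes_path),
        "vcf": str(vcf_path),
        "model": str(model_path),
        "genome": str(fasta_path),
        "depth_case": str(case_path),
        "depth_panel": ",".join(str(p) for p in panel_paths),
        "affected": "VI_2,VI_3,VI_4",
        "case_sample": "VI_2",
        "transcript_id": model.transcript_id,
        "out_dir": str(outdir / "out"),
        "seed": seed,
        "annot_hgvs_del": CANONICAL_HGVS,
        "pcr_longrange_forward": "1002300-1002319",
        "pcr_longrange_reverse": "1005421-1005440",
        "pcr_exon_forward": "1004140-1004159",
        "pcr_exon_reverse": "1004300-1004319",
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(
        "".join(f"{k}: {v}\n" for k, v in config.items())
    )
    return {
        "config": config_path,
        "truth": truth_path,
        "truth_set": truth,
        "genome": fasta_path,
        "model": model_path,
        "vcf": vcf_path,
        "genotypes": genotypes_path,
        "depth_case": case_path,
        "depth_panel": panel_paths,
    }
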