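"""Transcript coordinate frame and coding-DNA ("c.") coordinate algebra.

All genomic coordinates are 1-based inclusive (HGVS convention). Coding-DNA
positions number the CDS from the A of the initiator ATG through the last
base of the stop codon; intronic positions are expressed as a signed offset
from the nearest exon boundary (``c.294+139`` is 139 bases 3' of the exon
whose last coding base is c.294). 5'/3' UTR coordinates (``c.-k``/``c.*k``)
are out of scope and rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq


class GeneModelError(ValueError):
    """Base class for gene-model problems."""


class ValidationError(GeneModelError):
    """A transcript model violates one of its structural invariants."""


class CoordinateError(GeneModelError):
    """A coordinate is invalid for the model (out of CDS, out of intron, UTR)."""


class SequenceError(GeneModelError):
    """A nucleotide sequence problem (alphabet, internal stop, bounds)."""


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class CdsCoordinate:
    """A coding-DNA position: CDS base (1-based) plus signed intronic offset.

    ``offset == 0`` means the position is exonic; a positive offset counts
    into the intron downstream (3') of the exon ending at ``base``, a
    negative offset counts into the intron upstream (5') of the exon
    starting at ``base``.
    """

    base: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise CoordinateError(f"CDS base must be >= 1, got {self.base}")

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    @classmethod
    def parse(cls, text: str) -> "CdsCoordinate":
        m = re.fullmatch(r"(\d+)(?:\s*([+-])\s*(\d+))?", text.strip())
        if m is None:
            raise CoordinateError(f"cannot parse CDS coordinate {text!r}")
        base = int(m.group(1))
        offset = 0
        if m.group(2):
            offset = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
        return cls(base, offset)


class GenomeSequence:
    """In-memory reference: sequence name -> nucleotide string, 1-based.

    A sequence may start at a genomic position other than 1 (``starts``),
    which lets a synthetic reference carry only the genomic window it
    actually models; lookups outside the stored window are errors. The
    offset round-trips through FASTA via an ``offset=N`` token in the
    record description.
    """

    def __init__(self, sequences: dict[str, str], starts: dict[str, int] | None = None):
        self._seqs: dict[str, str] = {}
        self._starts: dict[str, int] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise SequenceError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)!r}"
                )
            self._seqs[name] = seq
            self._starts[name] = (starts or {}).get(name, 1)
            if self._starts[name] < 1:
                raise SequenceError(f"sequence {name!r} start must be >= 1")

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def names(self) -> list[str]:
        return list(self._seqs)

    def start(self, name: str) -> int:
        return self._starts[name]

    def end(self, name: str) -> int:
        return self._starts[name] + len(self._seqs[name]) - 1

    def sequence(self, name: str) -> str:
        """The full stored string for a sequence (window starts at start(name))."""
        return self._seqs[name]

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return bases ``start..end`` inclusive (1-based)."""
        if name not in self._seqs:
            raise SequenceError(f"unknown sequence {name!r}")
        if start > end:
            raise SequenceError(f"fetch start {start} > end {end}")
        if start < self.start(name) or end > self.end(name):
            raise SequenceError(
                f"fetch {name}:{start}-{end} outside stored window "
                f"{self.start(name)}-{self.end(name)}"
            )
        off = self._starts[name]
        return self._seqs[name][start - off : end - off + 1]

    def base(self, name: str, pos: int) -> str:
        return self.fetch(name, pos, pos)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        seqs: dict[str, str] = {}
        starts: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
            m = re.search(r"\boffset=(\d+)", rec.description)
            if m:
                starts[rec.id] = int(m.group(1))
        if not seqs:
            raise SequenceError(f"no FASTA records in {path}")
        return cls(seqs, starts)

    def to_fasta(self, path: str | Path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                header = f">{name}"
                if self._starts[name] != 1:
                    header += f" offset={self._starts[name]}"
                fh.write(header + "\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """Exon/intron/CDS geometry of one transcript on a genome.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order regardless of strand; ``cds_start``/``cds_end`` are the genomic
    positions of the genomically first/last coding base (cds_start <=
    cds_end; on the minus strand c.1 sits at ``cds_end``).
    """

    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    gene_id: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        self._validate()
        self._index()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError("model has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"exon interval reversed: {s}-{e}")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"exons overlap or are unsorted near genomic position {s}"
                )
            prev_end = e
        for pos, label in ((self.cds_start, "cds_start"), (self.cds_end, "cds_end")):
            if not any(s <= pos <= e for s, e in self.exons):
                raise ValidationError(f"{label} {pos} falls outside every exon")
        if self.cds_start > self.cds_end:
            raise ValidationError("cds_start must be <= cds_end (genomic order)")

    def _index(self) -> None:
        step = 1 if self.strand == "+" else -1
        tx_exons = self.exons if step == 1 else list(reversed(self.exons))
        # per tx-exon (5'->3') genomic coordinates of coding bases
        positions: list[int] = []
        self._exon_coding_range: list[tuple[int, int] | None] = []
        for s, e in tx_exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo > hi:
                self._exon_coding_range.append(None)
                continue
            first_c = len(positions) + 1
            if step == 1:
                positions.extend(range(lo, hi + 1))
            else:
                positions.extend(range(hi, lo - 1, -1))
            self._exon_coding_range.append((first_c, len(positions)))
        if len(positions) % 3 != 0:
            raise ValidationError(
                f"CDS length {len(positions)} is not divisible by 3"
            )
        self._step = step
        self._tx_exons = tx_exons
        self._cds_positions = positions
        self._g_to_c = {g: i + 1 for i, g in enumerate(positions)}

    # -- basic geometry -----------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self._cds_positions)

    @property
    def tx_exons(self) -> list[tuple[int, int]]:
        """Exons in transcription order (still (low, high) genomic tuples)."""
        return list(self._tx_exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def _exon_tx_bounds(self, i: int) -> tuple[int, int]:
        """(5' boundary, 3' boundary) genomic positions of tx-exon i."""
        s, e = self._tx_exons[i]
        return (s, e) if self._step == 1 else (e, s)

    def _intron_after(self, i: int) -> int:
        """Length of the intron following tx-exon i (transcription order)."""
        if i >= len(self._tx_exons) - 1:
            raise CoordinateError("no intron after the last exon")
        _, g3 = self._exon_tx_bounds(i)
        g5_next, _ = self._exon_tx_bounds(i + 1)
        return (g5_next - g3) * self._step - 1

    def _exon_index_of(self, g: int) -> int | None:
        for i, (s, e) in enumerate(self._tx_exons):
            if s <= g <= e:
                return i
        return None

    # -- coordinate algebra -------------------------------------------------

    def cds_to_genomic(self, c: CdsCoordinate) -> int:
        """Map a c. coordinate (with optional intronic offset) to genomic."""
        if not 1 <= c.base <= self.cds_length:
            raise CoordinateError(
                f"c.{c.base} outside CDS (length {self.cds_length})"
            )
        g = self._cds_positions[c.base - 1]
        if c.offset == 0:
            return g
        i = self._exon_index_of(g)
        assert i is not None
        g5, g3 = self._exon_tx_bounds(i)
        if c.offset > 0:
            if g != g3:
                raise CoordinateError(
                    f"positive offset requires the exon's 3' boundary; "
                    f"c.{c.base} is internal"
                )
            intron = self._intron_after(i)
            if c.offset > intron:
                raise CoordinateError(
                    f"offset +{c.offset} beyond intron of length {intron}"
                )
        else:
            if g != g5:
                raise CoordinateError(
                    f"negative offset requires the exon's 5' boundary; "
                    f"c.{c.base} is internal"
                )
            if i == 0:
                raise CoordinateError("no intron before the first exon")
            intron = self._intron_after(i - 1)
            if -c.offset > intron:
                raise CoordinateError(
                    f"offset {c.offset} beyond intron of length {intron}"
                )
        return g + c.offset * self._step

    def genomic_to_cds(self, g: int) -> CdsCoordinate:
        """Inverse map; intronic positions take the nearer-boundary convention.

        Distances at or below half the intron length anchor on the 5' exon
        as ``+k``; otherwise on the 3' exon as ``-k``.
        """
        c = self._g_to_c.get(g)
        if c is not None:
            return CdsCoordinate(c, 0)
        lo, hi = self.span
        if not lo <= g <= hi:
            raise CoordinateError(f"position {g} outside transcript span {lo}-{hi}")
        if self._exon_index_of(g) is not None:
            raise CoordinateError(
                f"position {g} is exonic but non-coding (UTR coordinates unsupported)"
            )
        for i in range(len(self._tx_exons) - 1):
            _, g3 = self._exon_tx_bounds(i)
            g5_next, _ = self._exon_tx_bounds(i + 1)
            d5 = (g - g3) * self._step
            d3 = (g5_next - g) * self._step
            if d5 >= 1 and d3 >= 1:
                rng_prev = self._exon_coding_range[i]
                rng_next = self._exon_coding_range[i + 1]
                if rng_prev is None or rng_next is None:
                    raise CoordinateError(
                        "intron flanked by a non-coding exon: UTR-side "
                        "intronic coordinates unsupported"
                    )
                intron = d5 + d3 - 1
                if 2 * d5 <= intron:
                    return CdsCoordinate(rng_prev[1], d5)
                return CdsCoordinate(rng_next[0], -d3)
        raise CoordinateError(f"position {g} not locatable within the transcript")

    def coding_c_positions_in(self, gstart: int, gend: int) -> list[int]:
        """Sorted c. positions of coding bases inside a genomic interval."""
        return sorted(c for g, c in self._g_to_c.items() if gstart <= g <= gend)

    # -- sequence -----------------------------------------------------------

    def cds_sequence(self, genome: GenomeSequence) -> str:
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                parts.append(genome.fetch(self.chrom, lo, hi))
        seq = "".join(parts)
        if self.strand == "-":
            seq = _revcomp(seq)
        return seq

    def check_sequence(self, genome: GenomeSequence) -> None:
        """Check the sequence-level invariant: one stop codon, at the 3' end."""
        seq = self.cds_sequence(genome)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        stops = [i for i, cod in enumerate(codons) if cod in _STOP_CODONS]
        if stops != [len(codons) - 1]:
            raise ValidationError(
                f"CDS must contain exactly one stop codon at its 3' end; "
                f"stop codon indices found: {stops}"
            )


def translate_cds(seq: str) -> str:
    """Translate a CDS with the standard code, dropping the terminal stop.

    An internal stop codon or a non-ACGT character is an error.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise SequenceError(f"non-ACGT characters in CDS: {sorted(bad)!r}")
    if len(seq) % 3 != 0:
        raise SequenceError(f"CDS length {len(seq)} not divisible by 3")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise SequenceError(
            f"internal stop codon at residue {protein.index('*') + 1}"
        )
    return protein


# -- model file I/O ---------------------------------------------------------

TSV_COLUMNS = ["chrom", "strand", "exon_index", "start", "end", "cds_flag"]


def load_transcript(model_file: str | Path, transcript_id: str) -> TranscriptModel:
    """Read a transcript from a GFF3 subset (exon+CDS features) or the TSV dialect.

    The TSV dialect has a header row ``chrom strand exon_index start end
    cds_flag``: rows with cds_flag=0 give exon boundaries, rows with
    cds_flag=1 give the coding sub-interval of the exon with the same index.
    """
    path = Path(model_file)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _load_gff3(path, transcript_id)
    return _load_tsv(path, transcript_id)


def _load_tsv(path: Path, transcript_id: str) -> TranscriptModel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"model TSV missing columns: {sorted(missing)}")
    if "transcript_id" in df.columns:
        df = df[df["transcript_id"] == transcript_id]
        if df.empty:
            raise ValidationError(f"transcript {transcript_id!r} not found in {path}")
    exon_rows = df[df["cds_flag"] == 0].sort_values("start")
    cds_rows = df[df["cds_flag"] == 1]
    if exon_rows.empty or cds_rows.empty:
        raise ValidationError("model TSV needs both exon (cds_flag=0) and CDS rows")
    return TranscriptModel(
        chrom=str(exon_rows["chrom"].iloc[0]),
        strand=str(exon_rows["strand"].iloc[0]),
        exons=[(int(r.start), int(r.end)) for r in exon_rows.itertuples()],
        cds_start=int(cds_rows["start"].min()),
        cds_end=int(cds_rows["end"].max()),
        gene_id=str(df["gene_id"].iloc[0]) if "gene_id" in df.columns else "",
        transcript_id=transcript_id,
    )


def _load_gff3(path: Path, transcript_id: str) -> TranscriptModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    chrom = strand = None
    gene_id = ""
    for feat in db.all_features():
        parents = feat.attributes.get("Parent", [])
        if transcript_id not in parents:
            continue
        chrom, strand = feat.seqid, feat.strand
        gene_id = feat.attributes.get("gene_id", [""])[0]
        if feat.featuretype == "exon":
            exons.append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds.append((feat.start, feat.end))
    if not exons:
        raise ValidationError(f"transcript {transcript_id!r} not found in {path}")
    if not cds:
        raise ValidationError(f"transcript {transcript_id!r} has no CDS features")
    exons.sort()
    return TranscriptModel(
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=min(s for s, _ in cds),
        cds_end=max(e for _, e in cds),
        gene_id=gene_id,
        transcript_id=transcript_id,
    )


def write_transcript_tsv(model: TranscriptModel, path: str | Path) -> None:
    lines = ["\t".join(TSV_COLUMNS + ["gene_id", "transcript_id"])]
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(
            f"{model.chrom}\t{model.strand}\t{i}\t{s}\t{e}\t0"
            f"\t{model.gene_id}\t{model.transcript_id}"
        )
        lo, hi = max(s, model.cds_start), min(e, model.cds_end)
        if lo <= hi:
            lines.append(
                f"{model.chrom}\t{model.strand}\t{i}\t{lo}\t{hi}\t1"
                f"\t{model.gene_id}\t{model.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_transcript_gff3(model: TranscriptModel, path: str | Path) -> None:
    tid, gid = model.transcript_id or "tx1", model.gene_id or "gene1"
    lo, hi = model.span
    rows = [
        "##gff-version 3",
        f"{model.chrom}\thomdel\tgene\t{lo}\t{hi}\t.\t{model.strand}\t.\tID={gid}",
        f"{model.chrom}\thomdel\tmRNA\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={tid};Parent={gid}",
    ]
    for i, (s, e) in enumerate(model.exons, start=1):
        rows.append(
            f"{model.chrom}\thomdel\texon\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={tid}.exon{i};Parent={tid};gene_id={gid}"
        )
        clo, chi = max(s, model.cds_start), min(e, model.cds_end)
        if clo <= chi:
            rows.append(
                f"{model.chrom}\thomdel\tCDS\t{clo}\t{chi}\t.\t{model.strand}\t0\t"
                f"ID={tid}.cds{i};Parent={tid};gene_id={gid}"
            )
    Path(path).write_text("\n".join(rows) + "\n")
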