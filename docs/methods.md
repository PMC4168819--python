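# Methods

## Coordinate conventions

All genomic coordinates are 1-based inclusive; BED output converts to
0-based half-open at the boundary. Coding-DNA ("c.") positions number the
CDS from the A of the initiator ATG through the last base of the stop
codon; intronic positions carry a signed offset from an exon boundary
(`c.294+139` = 139 bases 3' of the exon whose last coding base is c.294).
Positive offsets are only valid from an exon's 3' boundary, negative only
from a 5' boundary, and an offset may not exceed the intron length. UTR
coordinates (`c.-k`, `c.*k`) are rejected — they are not needed for
deletion annotation inside the coding region, and supporting them would
complicate the algebra for no benefit here.

The inverse map assigns an intronic genomic position to the nearer exon
boundary; an exact midpoint of an even-length intron goes to the 5' exon's
`+k` form. This tie-break is deterministic and matches common annotator
behaviour. Both strands are supported; minus-strand models mirror all the
arithmetic (the test suite checks that reflecting a model onto the
opposite strand leaves every c. coordinate invariant).

Transcript models are validated on construction: exons sorted and
non-overlapping, CDS endpoints inside exons, CDS length divisible by 3,
and (when the sequence is available) exactly one stop codon, at the 3'
end. Models load from a GFF3 subset (exon + CDS features, `Parent`
attributes; parsed with `gffutils`) or an equivalent TSV dialect.

## Deletion annotation

A deletion given as `c.<start>_<end>del` (whitespace tolerated around the
offset sign, as journals sometimes typeset it) is resolved to its genomic
span; the coding bases removed are the CDS positions inside the span, the
remainder is intronic. Frame status is `coding_bases_removed mod 3`. For
an in-frame deletion whose coding run starts and ends on codon boundaries
the protein consequence is `p.<aa1><r1>_<aa2><r2>del` with residues read
from the translated wild-type CDS; an in-frame deletion that is not
codon-aligned creates a novel junction residue and is reported with a
junction flag and no residue names (full HGVS indel grammar is out of
scope); a frameshift is reported with an `fs` marker. Deletions removing
the initiator or terminator codon are flagged unsupported rather than
silently annotated.

HGVS 3'-most normalization (shifting a deletion to its most-3' equivalent
position) is available but off by default: breakpoints determined directly
by sequencing are reported as observed. The synthetic genome pins the
bases flanking the planted breakpoints so that normalization is a no-op
there and both settings agree on the worked example.

In-silico PCR is purely positional: a primer pair is a pair of reference
footprints (15–35 nt, forward entirely 5' of reverse), the product length
is the distance from the forward 5' end to the reverse 3' end on the
queried allele, and a footprint overlapping a deletion breakpoint yields
no product. No melting-temperature or mismatch model is attempted — the
purpose is predicting product presence/length for alleles that differ by
a known structural variant. Genotype classification combines an
exon-internal assay with a deletion-spanning long-range assay per allele;
an allele with no product in either assay raises an assay-failure signal
(the positive-control logic of a diagnostic gel).

## ROH detection

A run of homozygosity is a maximal window of consecutive markers, bounded
by homozygous calls, containing at most `max_het` heterozygous and
`max_missing` missing calls; maximal means not contained in any other
qualifying window (two maximal runs may overlap across a tolerated
heterozygous call). Defaults — `min_markers=25`, `min_length_bp=1e6`
(length measured end − start), `max_het=1`, `max_missing=2` — target
multi-megabase autozygous segments at SNP-array marker density while
tolerating occasional genotyping error; all are configurable. Region size
in Mb is (end − start)/10⁶ rounded half-up to one decimal, matching how
region sizes are conventionally quoted from bounding marker positions.

The detector is verified against a brute-force enumeration of all maximal
qualifying windows on random matrices up to 200 markers. Shared candidate
regions are the maximal intervals covered by at least one ROH of every
affected sample (per-sample runs are unioned first; allele identity across
samples is not required, matching homozygosity-viewer behaviour). Regions
homozygous in unaffected relatives are not excluded by default.

## Variant filter cascade

Stage order: region restriction (caller-PASS records only, inclusive
bounds, regions merged first) → known-polymorphism removal → functional
class filter → tandem-repeat flagging. dbSNP membership and allele
frequency arrive as VCF INFO annotations (`DB129` flag, `AF137` float) so
the cascade needs no database access; the MAF threshold is inclusive
(≥ 1% dropped) and unknown MAF is retained — conservative for a discovery
pipeline. Functional classes are taken from the `FCLASS` annotation;
"splice consensus" is understood as the canonical ±2 intronic positions.
The repeat flag tests whether an indel's inserted/deleted sequence is a
whole multiple of a repeat unit (≤ 6 bp) present at least 4 times in the
reference tract adjacent to the anchor base; flagged records are annotated
`LIKELY_REPEAT_POLYMORPHISM` but never removed — deciding that such an
indel is an unlikely cause remains the analyst's call. The two
polymorphism/functional stages commute; per-stage counts are checked for
internal consistency.

## Coverage screen

Mean reads/base per exon is the sum of per-base depth over the exon
(uncovered bases count 0) divided by exon length; tracks are accepted as
per-base TSV or bedGraph. The panel summary per exon is the arithmetic
mean/min/max over ≥ 2 control samples, and the case ratio is
case/panel_mean. The verdict is `homozygous_deletion_candidate` when the
ratio ≤ `max_ratio` (default 0.1) and the panel mean ≥ `min_panel_depth`
(default 10 reads/base); exons the panel cannot vouch for are
`low_confidence` regardless of ratio. At panel-scale depth (~230
reads/base) Poisson noise cannot push a diploid exon's ratio near 0.1, and
a fully deleted exon with sub-1% mis-mapping noise cannot rise above it,
so the thresholds separate the two regimes by a wide margin — but a
heterozygous deletion (ratio ≈ 0.5) is deliberately NOT called: the screen
is homozygous-only, which the tests document explicitly. Raw means are
compared by default (no between-sample normalization); an optional
per-sample median scaling handles unequal library sizes. Reported ratios
are rounded to 4 decimals; verdicts are computed on unrounded values.

## Synthetic data: what it emulates, and what it does not

The canonical toy gene is a plus-strand 7-exon transcript on a 1.1 Mb
chromosome: CDS 1344 nt (447 codons + stop), per-exon CDS spans
60/60/60/60/54/237/813, intron lengths 500/500/500/500/1770/1000, gene
start at 1,000,001, CDS start at 1,000,051. Exon 5 ends at c.294 (genomic
1,002,344) and exon 6 spans c.295–531 (genomic 1,004,115–1,004,351), so
the deletion `c.294+139_531+478del` spans 1,002,483–1,004,829 = 2347 bp:
1632 bp of intron 5, all 237 bp of exon 6, 478 bp of intron 6. Codon 99 is
seeded TAT (Tyr) and codon 177 GAA (Glu). The intron-5 length (1770 bp) is
bookkeeping chosen so that these numbers are simultaneously consistent —
it is synthetic and not a measurement of any real gene. Non-gene sequence
is uniform random ACGT from a seeded generator.

Pedigree genotypes cover two marker chromosomes at 5 kb spacing with
background heterozygosity 0.35. Two shared autozygous segments (14.5 and
12.2 Mb) are planted in all three affected children, plus one private
segment per affected. Genotyping error (default 0.002) is modeled as an
allele-swap miscall (AA↔BB; a miscalled AB becomes a random homozygote),
so an autozygous tract remains a homozygous run; with error modeled as
spurious heterozygous calls instead, the detector's default 1-het-per-run
tolerance fragments multi-megabase segments at a non-trivial rate and
"number of shared regions" stops being a well-defined truth — call-level
het/missing tolerance is therefore exercised by dedicated tests with
explicitly constructed matrices rather than by the pedigree generator.
Unaffected relatives receive background genotypes (their carrier
haplotypes are not modeled at marker level). No linkage disequilibrium,
recombination-map realism or allele-frequency spectrum is simulated:
passing recovery tests shows the detector recovers planted segments under
idealized marker independence, not that the defaults are optimal for any
particular array product.

Depth tracks draw per-base depths independently: Poisson with mean
`mean_depth × copy_number/2`, except copy-0 exons which receive sparse
mis-mapping noise (Poisson, 0.24% of `mean_depth` — about 0.55 reads/base
at the default 230, i.e. near-zero but not zero). The bundled fixture uses
panel means (200, 210, 230, 250, 260) so the panel-wide mean is 230
reads/base. There is no read-length autocorrelation, GC bias or capture
efficiency variation, so real exome depth is substantially noisier than
these tracks.

The VCF generator plants, by default, 626 known/common records, 45 rare
records of silent classes and one rare (CGG)₅ insertion inside a (CGG)₈
reference tract — 672 caller-PASS in-region records of which 46 survive
the polymorphism filter and exactly 1 survives the functional filter,
flagged as a likely repeat polymorphism — plus non-PASS and
outside-region rejects. A synthetic reference window (region ± 2 Mb) is
generated per candidate-region chromosome and carried with a per-sequence
start offset (FASTA header token `offset=N`) so no multi-megabyte padding
is stored; outside-region records are placed ≥ 1 Mb from region bounds so
that detected-region boundary jitter (ROH bounds land on the outermost
homozygous markers, typically a few markers beyond a planted segment)
cannot change their classification.

All generators are deterministic given (parameters, seed);
regenerate-and-compare is bit-identical.

## Pipeline

`run_discovery` executes ROH → filter → coverage → annotation and emits a
JSON + text report whose regeneration from the same config is
byte-identical (provenance records the config hash, seed and package
version; no timestamps). Stage failures abort with the stage name and
leave a `FAILED` marker next to any partial outputs. Config files are
flat key-value YAML validated against a schema; all errors (types, ranges,
unknown keys with a nearest-match suggestion, missing files) are collected
and reported together. Exit codes: 0 = candidate found, 3 = clean run
without candidate, 1 = error.

Problem sizes used by the test suite and the acceptance script: the
canonical 1.1 Mb chromosome and 1344 nt CDS for all coordinate work; two
~6,000-marker chromosomes for ROH recovery; 100-seed loops for the
coverage-screen guarantees; a ~80-record VCF over a 1 Mb region for
cascade unit tests and the full 672-record composition for the end-to-end
fixture. The full suite runs in well under a minute on one CPU.

## Known limitations

- Single-transcript genes only; standard genetic code; no selenocysteine.
- No duplications, insertions or inversions; no splice-effect scoring.
- The coverage screen is single-exon and threshold-based — no multi-exon
  segmentation (XHMM/CoNIFER-style HMMs) and no heterozygous CNV calling.
- In-silico PCR assumes perfect primer hybridization at the reference
  footprint.
- ROH detection does not estimate inbreeding coefficients or perform
  linkage analysis; it is a run-finder with explicit tolerances.
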