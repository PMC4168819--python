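# homdel

Discovery and annotation of homozygous exon deletions in consanguineous
pedigrees, from SNP genotypes and exome read depth.

In a family with related parents, a recessive disease locus sits inside a
genomic segment that is autozygous — homozygous by descent — in every
affected child. `homdel` implements the full desk computation of that
mapping strategy as a tested, reusable library and CLI:

1. **ROH mapping** (`homdel.roh_mapping`) — detect maximal runs of
   homozygosity per sample from a biallelic SNP genotype matrix
   (tolerating a configurable number of heterozygous/missing calls per
   run) and intersect them across affected individuals into shared
   candidate regions.
2. **Rare-variant filter cascade** (`homdel.variant_filter`) — restrict a
   VCF to the candidate regions (caller-PASS only), remove known
   polymorphisms (early-dbSNP membership, or MAF ≥ 1% in a later build),
   keep protein-relevant classes (nonsynonymous, exonic indel, splice
   consensus), and flag surviving indels that sit in simple tandem-repeat
   tracts as likely repeat-number polymorphisms.
3. **Coverage screen** (`homdel.coverage_screen`) — per-exon mean
   reads/base for a case exome versus a control panel (≥ 2 exomes
   processed identically); an exon whose case/panel depth ratio is ≤ 0.1
   while the panel is ≥ 10 reads/base deep is a homozygous-deletion
   candidate.
4. **Deletion annotation** (`homdel.gene_model`,
   `homdel.deletion_annotation`) — HGVS coding-DNA coordinate algebra
   (`c.294+139` ⇄ genomic), genomic span / coding–intronic split /
   reading-frame status / `p.` protein consequence of a deletion, a VCF
   symbolic-DEL record, and positional in-silico PCR that predicts the
   diagnostic amplicons and genotype (wild type / carrier / homozygous
   deleted) per individual.

A deterministic synthetic-data module (`homdel.synthetic_data`) generates
every input with known ground truth — a toy genome hosting a 7-exon gene,
pedigree genotypes with planted autozygous segments, Poisson depth tracks
with a planted homozygous exon deletion, and an annotated VCF — so the
whole pipeline is testable end to end without any external data.

## Worked example

```bash
homdel simulate --outdir fixture --seed 7
homdel run-all --config fixture/config.yaml
```

prints

```
# discovery report
shared regions: 2
  chr1:11685000-26185000 (14.5 Mb, 2901 markers)
  chr4:71230000-83440000 (12.2 Mb, 2443 markers)
variant cascade:
  restrict_to_regions: 727 -> 672
  filter_known: 672 -> 46
  filter_functional: 46 -> 1
  flag_repeat_context: 1 -> 1
homozygous-deletion candidate exons: 1
  TOYGENE exon 6 (0.5274 vs panel 230.8979 reads/base)
deletion c.294+139_531+478del: 2347 bp (237 coding + 2110 intronic), in-frame, p.Tyr99_Glu177del, protein 447 -> 368 aa
in-silico PCR genotype classes:
  carrier_alleles: carrier
  deleted_alleles: homozygous_deleted
  wild_type_alleles: wild_type
```

Reading the report: the three affected siblings share exactly the two
planted autozygous regions (14.5 and 12.2 Mb). Of 672 caller-PASS variants
inside them, 46 are not known polymorphisms and a single protein-relevant
variant survives — an insertion flagged as a likely (CGG)n repeat
polymorphism, i.e. no convincing point mutation. The depth screen instead
shows exon 6 of the toy gene at 0.53 reads/base in the case against ~231
in the panel: a homozygous deletion. Annotating the deletion
`c.294+139_531+478del` gives a 2347 bp span removing all 237 coding bases
of exon 6 plus 2110 intronic bases — in frame, deleting residues
Tyr99–Glu177 (79 aa, protein 447 → 368) — and the exon 5 → exon 7
long-range PCR yields a 794 bp product only from deleted alleles, which
the genotype classifier turns into wild-type / carrier / homozygous calls.

`run-all` exits 0 when a candidate is found, 3 when none is, 1 on error.
Each stage is also available standalone (`homdel roh`,
`homdel filter-variants`, `homdel covscreen`, `homdel annotate`) on plain
TSV/BED/VCF/GFF3/FASTA files.

## Library use

```python
from homdel import (make_canonical_model, parse_hgvs_c_del,
                    annotate_deletion, apply_deletion, in_silico_pcr,
                    PrimerPair)

genome, model, _ = make_canonical_model(seed=1)
cons = annotate_deletion(
    parse_hgvs_c_del("c.294+139_531+478del", model), model, genome)
cons.total_length        # 2347
cons.protein_hgvs        # 'p.Tyr99_Glu177del'

allele = apply_deletion(genome, cons.chrom,
                        cons.genomic_start, cons.genomic_end)
in_silico_pcr(allele, PrimerPair("chrG", (1002300, 1002319),
                                 (1005421, 1005440)))   # 794
```

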