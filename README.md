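# trgermline

Population-matched germline allele inference for T-cell receptor (TR) loci
from phased whole-genome variant data.

## The problem

The four TR loci (*TRA*, *TRB*, *TRG*, *TRD*) carry the V, D, J and C gene
segments that recombine into T-cell receptor chains, flanked by recombination
signal sequences (RSS: a heptamer, a 12/23-bp spacer and a nonamer).  Curated
allele databases for these genes are biased toward well-studied populations
and often lack rare, population-specific variants.  Given a **phased** diploid
VCF for a cohort (e.g. a 1000 Genomes-style panel of thousands of samples
across 26 populations and 5 super-populations), a reference genome, a gene
annotation table and a known-allele database, this package infers the
germline alleles actually segregating in the cohort, together with their
haplotype support and population distribution.

The core idea: each diploid sample contributes exactly **two phased
haplotypes per gene** (a cohort of *n* samples yields 2*n*).  An **allele** is
an equivalence class of identical haplotype sequences across the cohort; its
**support** is the number of haplotypes in the class.  Alleles are sorted by
descending support, named `GENE_01, GENE_02, …`, and classified:

| category | definition |
|---|---|
| AS1 | matches a known database allele (support ≥ 4) |
| AS2 | novel, frequent: support ≥ 19 haplotypes (≥ 10 individuals) |
| AS3 | novel, rare: support 4–18 |
| discarded | support < 4 |

Two curation filters remove likely artifacts: alleles whose coding
translation contains an internal stop codon, and alleles of **operationally
indistinguishable (OI) genes** — V paralogs sharing a neighbor-joining clade
with branch lengths ≤ 0.02, where short-read mis-mapping can duplicate a
mutation across paralogs.  A novel-allele mutation shared (at the aligned
position, same base) between two OI paralogs is removed unless it also occurs
in a known database allele.

Retained alleles are annotated by super-population presence — `ALL`, `AFR`
(Africans only), `AFR_SHARED`, `NON_AFR` — and each locus is summarized by a
genotype PCA over its biallelic SNPs and by pairwise Hudson F<sub>ST</sub>
between populations (Weir–Cockerham available), visualized as an NJ
cladogram.

## Worked example

Everything below runs offline: the `simulate` subcommand generates a seeded
miniature locus (6 V genes, 4 populations × 50 diploid samples, 12 planted
alleles, an injected OI gene pair) with a ground-truth table.

```sh
trgermline simulate --outdir fixture --seed 7
trgermline run \
    --vcf fixture/cohort.vcf --reference fixture/reference.fa \
    --annotation fixture/annotation.tsv --panel fixture/panel.tsv \
    --known-db fixture/known_db.fa --outdir out
```

which prints

```
wrote fixture to fixture: 200 samples, 6 genes, 18 truth alleles
wrote out (16 alleles kept, 2 removed)
```

200 diploid samples give 400 haplotypes per gene; collapsing them yields 18
distinct alleles (the 6 reference alleles plus the 12 planted ones).  The two
removed alleles are the planted OI artifacts — the same mutation at the same
aligned position in both members of the near-identical gene pair `TRAV5`/
`TRAV6` — while the planted shared mutation that also occurs in a known
database allele is rescued and kept.  `out/alleles.tsv` lists, per allele,
the support, AS category, nearest known allele, mutation count (complete and
V-exon-only), synonymous/non-synonymous counts and population category;
`out/population_distribution.tsv`, `out/rss.tsv`, `out/fst_chrS.tsv`,
`out/pca_chrS.tsv` and the newick trees carry the rest of the outputs.

## Layout

- `trgermline.locus_model` — domain types and I/O (annotation TSV, panel TSV,
  known-allele FASTA, reference FASTA); coordinate/strand normalization.
- `trgermline.haplotyper` — phased-variant application, per-gene haplotype
  reconstruction.
- `trgermline.allele_caller` — collapsing, naming, classification,
  database matching, mutation profiles, syn/nonsyn counts, RSS records.
- `trgermline.curation` — stop-codon filter, NJ trees, OI-gene detection,
  shared-mutation filter.
- `trgermline.popgen` — population annotation, genotype matrix, PCA,
  pairwise F<sub>ST</sub>, F<sub>ST</sub> cladogram.
- `trgermline.synthetic_locus` — the seeded fixture generator and truth
  tables.
- `trgermline.pipeline` / `trgermline.cli` — orchestration, allele-set
  comparison, summaries, `trgermline` command-line entry point.

See `docs/methods.md` for the model, parameter defaults and limitations.
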