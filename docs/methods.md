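# Methods

## Model and procedure

The method treats germline allele discovery as exact haplotype enumeration
rather than statistical genotyping.  Phasing is taken as given: for every
annotated gene the two parental sequences of each diploid sample are rebuilt
by splicing the gene's exons out of the reference (reverse-complemented for
minus-strand genes, so all sequences read 5'→3' in transcription
orientation) and substituting the sample's phased variants, applied
right-to-left within each genomic interval so indels never invalidate
downstream coordinates.  Identical haplotype sequences across the cohort are
collapsed into alleles; all downstream quantities (support, classification,
population distribution) are functions of this partition, so the count
invariant Σ allele support = 2 × n samples holds exactly per gene.

Classification thresholds (support ≥ 4 to call an allele; ≥ 19 haplotypes,
i.e. ≥ 10 individuals, to call a novel allele "frequent") are cohort-scale
conventions for a ~2,500-sample panel; both are exposed
(`min_support`, `frequent_support`) and enforced boundary-exactly.  A known
match makes an allele AS1 regardless of how frequent it is, as long as it
clears `min_support`.

### Database matching and partial records

Known-allele databases routinely store V alleles without the leader exon.
In `complete` mode a leaderless record is compared over its covered region
only (the V exon), reported as `overlap_partial`; a consequence, accepted
deliberately, is that leader-only differences from such records do not block
a match, and mutation counts against a leaderless nearest allele cannot see
leader positions.  Running the pipeline in `v_exon_only` mode merges alleles
that differ only in the leader — the merging property tested in the suite.

### Mutation profiles

The nearest known allele minimizes the mutation count, ties broken by the
lowest allele number.  Equal-length sequences are compared per position;
otherwise a unit-cost global alignment (affine gaps, so one indel event is
one event) is used and each indel event counts as a single mutating
position.  Counts are reported for the complete sequence and the V exon
separately.  Synonymous/non-synonymous counts translate both coding
sequences in the annotated frame with the standard code and compare codons;
an internal stop is flagged and left to curation.

### Curation

1. **Stop-codon filter** — alleles of functional/ORF genes with an internal
   stop are removed; pseudogenes are exempt (their alleles and RSS remain of
   interest).
2. **OI filter** — per locus, an NJ tree (Saitou–Nei, negative branches
   clamped to zero) is built over V-gene reference p-distances.  "Sharing a
   clade with a short branch length" is operationalized as: two genes are
   OI-related when every branch on the unrooted tip-to-tip path is ≤ the
   threshold (default 0.02); maximal groups are connected components of that
   relation.  The alternative reading — total path length ≤ threshold — is
   available as `branch_rule="path_sum"`.  Within a group, novel alleles are
   mapped to a common coordinate frame by aligning gene references; a novel
   allele is removed iff one of its mutations (aligned position + base)
   recurs in a novel allele of another member gene and does not occur in any
   known database allele of the group (the rescue clause).  Known-matching
   alleles are never removed.  The two filters commute.

p-distance (no multiple-hit correction) is used because intra-locus V
paralogs are closely related and the 0.02 threshold is calibrated on raw
similarity; corrections would only matter at divergences far above it.

### Population annotation

Category assignment uses presence ≥ 1 haplotype per super-population so
that category and counts stay consistent; the per-population boolean
presence flags use a separate threshold (default 4, the heat-map
convention).  The four categories (ALL / AFR / AFR_SHARED / NON_AFR) are
defined against the set of super-populations present in the panel, which
generalizes the 5-super-population definition to smaller synthetic panels;
with a full panel the two definitions coincide.

### Locus-level diversity

The genotype matrix keeps biallelic segregating SNPs over the locus span
(coding and non-coding).  PCA mean-centers dosages and, by default, scales
each site by √(p(1−p)) — the usual genotype-PCA normalization; raw-dosage
PCA is available (`scale=False`).  Component signs are fixed by making the
largest-magnitude loading positive.  Pairwise F<sub>ST</sub> defaults to the
Hudson estimator as a ratio of averages across sites, which is robust to
unequal sample sizes across many populations; Weir–Cockerham is available
and agrees closely at equal sizes.  Negative pairwise values are clamped to
zero for the NJ cladogram; raw values are retained in the matrix output.

## Synthetic cohorts

The generator emulates the pipeline's input universe at desk scale: a
seeded contig carrying V genes with leader (48 bp, ATG-initiated) + V exon
(288 bp) structure and a 3' RSS (canonical CACAGTG heptamer, 23-bp spacer,
canonical nonamer), some genes minus-strand; a diploid cohort (default
4 populations × 50 samples across the AFR/AMR/EAS/EUR super-populations)
whose haplotypes draw alleles independently from designed per-population
frequencies; and a phased VCF that encodes every haplotype exactly.  The
default plan plants 12 non-reference alleles chosen to realize every AS
category and every population category at these sample sizes, plus an OI
pair: two genes at p-distance ≈ 0.015 carrying one shared artifact mutation
(absent from the database) and one shared mutation rescued by a database
record.  Coding sequences and planted mutations are constructed stop-free so
the planted truth is not confounded with the stop-codon filter.

What the generator does **not** emulate: linkage disequilibrium beyond
allele identity (haplotypes are drawn independently), sequencing or phasing
error, read-level mis-mapping (the OI artifact is planted directly),
structural variation, and realistic locus architecture (D/J/C segments,
pseudogene content).  Passing tests therefore demonstrate the correctness of
the enumeration, classification, filtering and annotation logic under ideal
phased input — not robustness to upstream calling or phasing error, which
on real data dominates the error budget.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open; files use 1-based inclusive.
  Conversion happens only at I/O boundaries.
- Equal-support ties in allele naming are broken lexicographically by
  sequence, making naming a total deterministic order.
- Unphased heterozygous genotypes are a hard error by default (the method
  is undefined without phasing); a per-sample skip is available.  Missing
  genotypes are treated as reference with a warning.
- Indels are applied like SNPs by default; `snps_only` restricts to SNPs.
  Variants straddling an exon boundary are flagged and clipped to the
  spliced interval.
- Deterministic outputs: identical config + inputs give byte-identical
  tables (a config hash is embedded in output headers for provenance).
- Problem sizes in the test suite and acceptance script (200-sample
  cohorts, 6 genes, 336-bp genes, ≤ 40-site F<sub>ST</sub> matrices) keep
  the full check suite around a second while exercising every code path;
  the pipeline itself streams per-gene and scales linearly in samples ×
  variants.

## Known limitations

- Allele identity is exact string equality; a single phasing switch error
  splits an allele into two.  On real cohorts the support thresholds absorb
  some of this, but the package does not model it.
- The OI shared-mutation filter maps positions across paralogs via pairwise
  global alignment of gene references; highly diverged "paralogs" (which
  would not be OI in the first place) could map ambiguously.
- F<sub>ST</sub> estimators use allele counts assuming within-population
  Hardy–Weinberg for the heterozygosity term of Weir–Cockerham; the Hudson
  default does not need it.
- The RSS model is the classic heptamer + 12/23 spacer + nonamer; atypical
  spacers are rejected at annotation load.
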