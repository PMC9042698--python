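"""Phased haplotype reconstruction.

For every gene and every sample the two parental gene sequences are rebuilt
by applying the sample's phased variants to the spliced reference sequence.
A diploid sample therefore contributes exactly two haplotypes per gene; this
count conservation (2 × n samples) is the backbone invariant of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pysam

from .locus_model import GeneAnnotation, PopulationPanel, extract_gene_reference, revcomp

log = logging.getLogger(__name__)


class PhasingError(ValueError):
    """Unphased or half-called genotype where phasing is required."""


class VariantApplicationError(ValueError):
    """Conflicting or invalid variant application on one haplotype."""


@dataclass
class PhasedVariantRecord:
    """One VCF record restricted to what haplotype building needs.

    ``position`` is 1-based (VCF convention); ``start`` is the 0-based
    genomic coordinate.  ``genotypes`` maps sample id to the pair of allele
    indices in VCF order (paternal|maternal as phased in the source).
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, tuple[int, int]]
    boundary_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.alt_alleles or any(not a for a in self.alt_alleles):
            raise ValueError(f"{self.chromosome}:{self.position}: empty ALT allele")

    @property
    def start(self) -> int:
        return self.position - 1

    @property
    def end(self) -> int:
        return self.start + len(self.ref_allele)

    def allele_index(self, sample: str, phase_index: int) -> int:
        return self.genotypes[sample][phase_index]


@dataclass
class HaplotypeSequence:
    """One phased gene sequence from one parental chromosome of one sample."""

    sample_id: str
    phase_index: int  # 0 or 1, strand order as in the VCF
    gene_name: str
    region_mode: str
    sequence: str
    #: applied variants in gene-local transcription coordinates (0-based)
    applied_variants: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase_index not in (0, 1):
            raise ValueError("phase_index must be 0 or 1")
        if not self.sequence:
            raise ValueError("empty haplotype sequence")
        self.applied_variants = sorted(self.applied_variants)

    @property
    def fasta_header(self) -> str:
        return f"{self.sample_id}|{self.phase_index}|{self.gene_name}"


def _intersects(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def variants_in_region(
    vcf: str | Path | Sequence[PhasedVariantRecord],
    ann: GeneAnnotation,
    region_mode: str = "complete",
    *,
    snps_only: bool = False,
    on_unphased: str = "error",
) -> list[PhasedVariantRecord]:
    """Phased records whose REF span intersects the gene's spliced intervals.

    ``vcf`` may be a path to a VCF 4.x file (plain or bgzipped) or an already
    loaded record list.  Heterozygous unphased genotypes raise
    :class:`PhasingError` unless ``on_unphased='skip_sample'``, which drops
    the offending sample from the record with a warning.
    """
    if on_unphased not in ("error", "skip_sample"):
        raise ValueError("on_unphased must be 'error' or 'skip_sample'")
    intervals = ann.intervals(region_mode)
    out: list[PhasedVariantRecord] = []
    for rec in _iter_records(vcf, ann.chromosome, on_unphased):
        if rec.chromosome != ann.chromosome:
            continue
        if snps_only and (len(rec.ref_allele) != 1 or any(len(a) != 1 for a in rec.alt_alleles)):
            continue
        hit = [iv for iv in intervals if _intersects(rec.start, rec.end, *iv)]
        if not hit:
            continue
        rec.boundary_overlap = any(
            rec.start < s or rec.end > e for s, e in hit
        )
        out.append(rec)
    out.sort(key=lambda r: r.position)
    return out


def _iter_records(vcf, chromosome: str, on_unphased: str):
    if not isinstance(vcf, (str, Path)):
        yield from vcf
        return
    with pysam.VariantFile(str(vcf)) as vf:
        for rec in vf:
            if rec.chrom != chromosome or rec.alts is None:
                continue
            gts: dict[str, tuple[int, int]] = {}
            for sample, call in rec.samples.items():
                gt = call["GT"]
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    log.warning(
                        "missing genotype at %s:%d for %s, treated as reference",
                        rec.chrom, rec.pos, sample,
                    )
                    gts[sample] = (0, 0)
                    continue
                if not call.phased and gt[0] != gt[1]:
                    if on_unphased == "error":
                        raise PhasingError(
                            f"unphased heterozygous genotype at {rec.chrom}:{rec.pos} "
                            f"for sample {sample}"
                        )
                    log.warning(
                        "skipping sample %s at %s:%d (unphased)", sample, rec.chrom, rec.pos
                    )
                    continue
                gts[sample] = (gt[0], gt[1])
            yield PhasedVariantRecord(
                chromosome=rec.chrom,
                position=rec.pos,
                ref_allele=rec.ref.upper(),
                alt_alleles=tuple(a.upper() for a in rec.alts),
                genotypes=gts,
            )


def apply_phased_variants(
    reference: Mapping[str, str],
    ann: GeneAnnotation,
    variants: Sequence[PhasedVariantRecord],
    sample_id: str,
    phase_index: int,
    region_mode: str = "complete",
) -> HaplotypeSequence:
    """Build one haplotype by applying a sample's phased variants.

    Variants are applied right-to-left within each genomic interval so that
    earlier coordinates stay valid under indels; the spliced result is
    reverse-complemented for minus-strand genes, and applied variants are
    reported in gene-local transcription coordinates (positions, REF and ALT
    all in the transcription orientation).
    """
    contig = reference[ann.chromosome]
    intervals = ann.intervals(region_mode)
    offsets = []
    off = 0
    for s, e in intervals:
        offsets.append(off)
        off += e - s
    total = off

    # detect overlapping application on this haplotype
    active = [
        v for v in variants if v.allele_index(sample_id, phase_index) > 0
    ]
    for v in active:
        idx = v.allele_index(sample_id, phase_index)
        if idx > len(v.alt_alleles):
            raise VariantApplicationError(
                f"{v.chromosome}:{v.position}: genotype index {idx} exceeds "
                f"{len(v.alt_alleles)} ALT alleles"
            )
    for a, b in zip(active, active[1:]):
        if _intersects(a.start, a.end, b.start, b.end):
            raise VariantApplicationError(
                f"overlapping variants on one haplotype: "
                f"{a.chromosome}:{a.position} and {b.chromosome}:{b.position}"
            )

    pieces: list[str] = []
    applied_splice: list[tuple[int, str, str]] = []  # splice-coordinate records
    for (s, e), ioff in zip(intervals, offsets):
        seq = contig[s:e]
        here = [v for v in active if _intersects(v.start, v.end, s, e)]
        for v in sorted(here, key=lambda v: v.start, reverse=True):
            alt = v.alt_alleles[v.allele_index(sample_id, phase_index) - 1]
            ref = v.ref_allele
            vs, ve = v.start, v.end
            if vs < s:
                # allele anchored left of the interval: only the in-interval
                # deleted reference tail is removable here
                trim = s - vs
                ref = ref[trim:]
                alt = ""
                vs = s
            if ve > e:
                ref = ref[: e - vs]
            seq = seq[: vs - s] + alt + seq[vs - s + len(ref):]
            applied_splice.append((ioff + (vs - s), ref, alt))
        pieces.append(seq)
    hap = "".join(pieces)

    if ann.strand == "-":
        hap = revcomp(hap)
        applied = [
            (total - (pos + len(ref)), revcomp(ref), revcomp(alt))
            for pos, ref, alt in applied_splice
        ]
    else:
        applied = applied_splice
    return HaplotypeSequence(
        sample_id=sample_id,
        phase_index=phase_index,
        gene_name=ann.gene_name,
        region_mode=region_mode,
        sequence=hap,
        applied_variants=applied,
    )


def reconstruct_gene_haplotypes(
    vcf: str | Path | Sequence[PhasedVariantRecord],
    reference: Mapping[str, str],
    ann: GeneAnnotation,
    panel: PopulationPanel,
    region_mode: str = "complete",
    *,
    snps_only: bool = False,
    on_unphased: str = "error",
    strict_samples: bool = True,
) -> list[HaplotypeSequence]:
    """Both phased haplotypes of every panel sample for one gene.

    Returns exactly 2 × n haplotypes for the n panel samples found in the
    VCF.  With ``strict_samples`` (default) a panel sample absent from the
    VCF is an error; otherwise it is dropped with a warning.  A gene with no
    overlapping variants yields 2 × n copies of the reference sequence.
    """
    variants = variants_in_region(
        vcf, ann, region_mode, snps_only=snps_only, on_unphased=on_unphased
    )
    vcf_samples: Optional[set[str]] = None
    if variants:
        # with skip_sample downgrades a sample may be absent from some records
        vcf_samples = set.intersection(*(set(v.genotypes) for v in variants))
    elif isinstance(vcf, (str, Path)):
        with pysam.VariantFile(str(vcf)) as vf:
            vcf_samples = set(vf.header.samples)

    samples = list(panel.samples)
    if vcf_samples is not None:
        missing = [s for s in samples if s not in vcf_samples]
        if missing:
            if strict_samples:
                raise ValueError(
                    f"{len(missing)} panel sample(s) missing from VCF, e.g. {missing[:3]}"
                )
            log.warning("%d panel sample(s) missing from VCF; skipped", len(missing))
            samples = [s for s in samples if s not in missing]
        if not samples:
            raise ValueError("no overlap between panel and VCF samples")

    ref_seq = extract_gene_reference(reference, ann, region_mode)
    haps: list[HaplotypeSequence] = []
    for sample in samples:
        for phase in (0, 1):
            if variants:
                haps.append(
                    apply_phased_variants(reference, ann, variants, sample, phase, region_mode)
                )
            else:
                haps.append(
                    HaplotypeSequence(sample, phase, ann.gene_name, region_mode, ref_seq)
                )
    return haps


def write_haplotype_fasta(haps: Sequence[HaplotypeSequence], path: str | Path) -> None:
    """Export haplotypes with ``sample|phase|gene`` headers."""
    with open(path, "w") as fh:
        for h in haps:
            fh.write(f">{h.fasta_header}\n{h.sequence}\n")
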