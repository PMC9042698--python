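"""Collapse haplotypes into alleles, classify and profile them.

An allele here is the equivalence class of byte-identical haplotype
sequences of one gene across the cohort; its support is the number of
haplotypes in the class.  Alleles are sorted by descending support and named
``GENE_01``, ``GENE_02``, ...  Support and a match against the known
(IMGT-style) database drive the three-way classification:

* **AS1** — matches a known database allele (support ≥ min_support);
* **AS2** — novel and frequent (support ≥ 19 haplotypes, i.e. ≥ 10 individuals);
* **AS3** — novel and rare (support 4-18);
* alleles below the minimum support (default 4) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .haplotyper import HaplotypeSequence
from .locus_model import (
    CANONICAL_HEPTAMER,
    HEPTAMER_LEN,
    NONAMER_LEN,
    GeneAnnotation,
    KnownAlleleDB,
    extract_gene_reference,
)

log = logging.getLogger(__name__)

MIN_SUPPORT = 4
FREQUENT_SUPPORT = 19


@dataclass
class KnownMatch:
    allele_id: str
    match_mode: str  # complete | v_exon_only | overlap_partial


@dataclass
class AlleleCall:
    """One collapsed haplotype class with support, classification and profile."""

    gene_name: str
    sequence: str
    haplotype_count: int
    supporting_haplotypes: list[tuple[str, int]]
    allele_id: str = ""
    region_mode: str = "complete"
    category: str = "unclassified"
    known_match: Optional[KnownMatch] = None
    nearest_known: Optional[str] = None
    mutations_vs_nearest_known: list[tuple[int, str, str]] = field(default_factory=list)
    mutation_count_v_exon: int = 0
    n_nonsynonymous: int = 0
    n_synonymous: int = 0
    has_internal_stop: bool = False
    applied_variants: list[tuple[int, str, str]] = field(default_factory=list)
    filter_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.haplotype_count != len(self.supporting_haplotypes):
            raise ValueError("haplotype_count must equal |supporting_haplotypes|")


@dataclass
class RSSRecord:
    """Recombination signal sequence of one gene side, with per-allele variants."""

    gene_name: str
    side: str
    heptamer: str
    spacer_length: int
    nonamer: str
    variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    conserved_heptamer: bool = False

    def __post_init__(self) -> None:
        if len(self.heptamer) != HEPTAMER_LEN or len(self.nonamer) != NONAMER_LEN:
            raise ValueError("heptamer/nonamer length fixed at 7/9")
        if self.spacer_length not in (12, 23):
            raise ValueError("spacer length must be 12 or 23")


# ---------------------------------------------------------------------------
# collapse / name / classify
# ---------------------------------------------------------------------------

def collapse_haplotypes(haps: Sequence[HaplotypeSequence]) -> list[AlleleCall]:
    """One AlleleCall per distinct sequence; counts partition the input."""
    genes = {h.gene_name for h in haps}
    if len(genes) > 1:
        raise ValueError(f"haplotypes from multiple genes: {sorted(genes)}")
    modes = {h.region_mode for h in haps}
    if len(modes) > 1:
        raise ValueError(f"haplotypes from multiple region modes: {sorted(modes)}")
    by_seq: dict[str, list[HaplotypeSequence]] = {}
    for h in haps:
        by_seq.setdefault(h.sequence, []).append(h)
    calls = []
    for seq, members in by_seq.items():
        calls.append(
            AlleleCall(
                gene_name=members[0].gene_name,
                sequence=seq,
                haplotype_count=len(members),
                supporting_haplotypes=[(m.sample_id, m.phase_index) for m in members],
                region_mode=members[0].region_mode,
                applied_variants=list(members[0].applied_variants),
            )
        )
    return calls


def sort_and_name(gene_name: str, alleles: Sequence[AlleleCall]) -> list[AlleleCall]:
    """Sort descending by support (ties lexicographic by sequence) and assign ids.

    Ids are ``GENE_01``-style, zero-padded to two digits (three past 99).
    """
    ordered = sorted(alleles, key=lambda a: (-a.haplotype_count, a.sequence))
    width = 2 if len(ordered) < 100 else 3
    for i, a in enumerate(ordered, start=1):
        a.allele_id = f"{gene_name}_{i:0{width}d}"
    return ordered


def classify(
    allele: AlleleCall,
    min_support: int = MIN_SUPPORT,
    frequent_support: int = FREQUENT_SUPPORT,
) -> str:
    """Total classification: discarded < min_support; AS1 if known; AS2/AS3 by support."""
    if allele.haplotype_count < min_support:
        allele.category = "discarded"
    elif allele.known_match is not None:
        allele.category = "AS1"
    elif allele.haplotype_count >= frequent_support:
        allele.category = "AS2"
    else:
        allele.category = "AS3"
    return allele.category


# ---------------------------------------------------------------------------
# known-database matching
# ---------------------------------------------------------------------------

def match_known(
    allele: AlleleCall,
    db: KnownAlleleDB,
    ann: GeneAnnotation,
    region_mode: str = "complete",
) -> Optional[KnownMatch]:
    """Match an allele sequence against the known database.

    In ``complete`` mode a complete known record must equal the full
    sequence; a leaderless (partial) known record is compared over the
    V-exon part only (match_mode ``overlap_partial``).  In ``v_exon_only``
    mode the comparison is restricted to the V exon on both sides.
    """
    records = db.alleles_for(allele.gene_name)
    if not records:
        log.debug("gene %s absent from known database", allele.gene_name)
        allele.known_match = None
        return None
    leader_len = ann.leader_length
    match: Optional[KnownMatch] = None
    for rec in sorted(records, key=lambda r: r.number):
        if region_mode == "complete":
            if rec.has_leader:
                if allele.sequence == rec.sequence:
                    match = KnownMatch(rec.allele_id, "complete")
                    break
            else:
                if allele.sequence[leader_len:] == rec.sequence:
                    match = KnownMatch(rec.allele_id, "overlap_partial")
                    break
        elif region_mode == "v_exon_only":
            known_v = rec.sequence[leader_len:] if rec.has_leader else rec.sequence
            query = allele.sequence
            if len(query) != len(known_v) and len(query) == leader_len + len(known_v):
                query = query[leader_len:]
            if query == known_v:
                match = KnownMatch(rec.allele_id, "v_exon_only")
                break
        else:
            raise ValueError(f"unsupported region mode for matching: {region_mode}")
    allele.known_match = match
    return match


# ---------------------------------------------------------------------------
# mutation profiling
# ---------------------------------------------------------------------------

def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    # affine gaps so one indel event stays one event
    aligner.open_gap_score = -1.5
    aligner.extend_gap_score = -0.5
    return aligner


def diff_sequences(query: str, subject: str) -> list[tuple[int, str, str]]:
    """Mutations of ``query`` relative to ``subject`` as (subject position, ref, alt).

    Equal-length sequences are compared position by position; otherwise a
    unit-cost global alignment is used and each indel event counts as one
    mutating position (anchored at the subject coordinate where it starts).
    """
    if len(query) == len(subject):
        return [
            (i, s, q) for i, (q, s) in enumerate(zip(query, subject)) if q != s
        ]
    aln = _global_aligner().align(subject, query)[0]
    muts: list[tuple[int, str, str]] = []
    s_coords, q_coords = aln.aligned
    prev_s, prev_q = 0, 0
    for (ss, se), (qs, qe) in zip(s_coords, q_coords):
        if ss > prev_s or qs > prev_q:
            muts.append((prev_s, subject[prev_s:ss], query[prev_q:qs]))
        for off in range(se - ss):
            if subject[ss + off] != query[qs + off]:
                muts.append((ss + off, subject[ss + off], query[qs + off]))
        prev_s, prev_q = se, qe
    if prev_s < len(subject) or prev_q < len(query):
        muts.append((prev_s, subject[prev_s:], query[prev_q:]))
    return sorted(muts)


def mutation_profile(
    allele: AlleleCall,
    db: KnownAlleleDB,
    ann: GeneAnnotation,
) -> tuple[Optional[str], list[tuple[int, str, str]], dict[str, int]]:
    """Nearest known allele, mutation list and per-region mutation counts.

    The nearest known allele minimizes the mutation count (ties broken by the
    lowest allele number).  Counts are reported for the complete sequence and
    for the V exon only; for a gene absent from the database the profile is
    computed against the gene reference and flagged via ``nearest = None``.
    """
    records = db.alleles_for(allele.gene_name)
    leader_len = ann.leader_length if allele.region_mode == "complete" else 0
    best: Optional[tuple[int, int, str, list]] = None
    for rec in records:
        if allele.region_mode == "complete":
            if rec.has_leader:
                subject, query, offset = rec.sequence, allele.sequence, 0
            else:  # leaderless record: compare over its covered (V-exon) region
                subject, query, offset = rec.sequence, allele.sequence[leader_len:], leader_len
        else:
            subject = rec.sequence[ann.leader_length:] if rec.has_leader else rec.sequence
            query, offset = allele.sequence, 0
        muts = [(p + offset, r, a) for p, r, a in diff_sequences(query, subject)]
        key = (len(muts), rec.number)
        if best is None or key < (best[0], best[1]):
            best = (len(muts), rec.number, rec.allele_id, muts)
    if best is None:
        allele.nearest_known = None
        muts = allele.mutations_vs_nearest_known = list(
            (p, r, a) for p, r, a in allele.applied_variants
        )
    else:
        allele.nearest_known = best[2]
        muts = allele.mutations_vs_nearest_known = best[3]
    v_exon_count = sum(1 for p, _, _ in muts if p >= leader_len)
    allele.mutation_count_v_exon = v_exon_count
    counts = {"complete": len(muts), "v_exon_only": v_exon_count}
    return allele.nearest_known, muts, counts


def count_nonsynonymous(
    allele_seq: str, reference_seq: str, ann: GeneAnnotation
) -> tuple[int, int, bool]:
    """(n_synonymous, n_nonsynonymous, internal_stop) between two coding sequences.

    Both sequences are translated from ``ann.coding_frame_offset`` with the
    standard genetic code; codons whose nucleotides differ count as
    synonymous when the amino acid is unchanged, non-synonymous otherwise.
    An internal stop in the allele's translation is flagged (the curation
    stage decides what to do with it), and comparison stops at it.
    """
    off = ann.coding_frame_offset
    a = allele_seq[off:]
    r = reference_seq[off:]
    n = min(len(a), len(r)) // 3 * 3
    aa_a = str(Seq(a[:n]).translate())
    aa_r = str(Seq(r[:n]).translate())
    internal_stop = "*" in aa_a[:-1]
    n_syn = n_nonsyn = 0
    for i in range(n // 3):
        codon_a, codon_r = a[3 * i: 3 * i + 3], r[3 * i: 3 * i + 3]
        if codon_a == codon_r:
            continue
        if aa_a[i] == aa_r[i]:
            n_syn += 1
        else:
            n_nonsyn += 1
    return n_syn, n_nonsyn, internal_stop


def annotate_alleles(
    alleles: Sequence[AlleleCall],
    db: KnownAlleleDB,
    ann: GeneAnnotation,
    reference_seq: str,
    *,
    min_support: int = MIN_SUPPORT,
    frequent_support: int = FREQUENT_SUPPORT,
) -> list[AlleleCall]:
    """Full per-allele annotation: match, classify, profile, syn/nonsyn counts."""
    out = sort_and_name(ann.gene_name, list(alleles))
    for a in out:
        match_known(a, db, ann, a.region_mode)
        classify(a, min_support, frequent_support)
        mutation_profile(a, db, ann)
        baseline = None
        if a.nearest_known is not None:
            for rec in db.alleles_for(a.gene_name):
                if rec.allele_id == a.nearest_known:
                    baseline = rec.sequence if rec.has_leader else None
        if baseline is None:
            baseline = reference_seq
        if ann.functionality != "pseudogene" and len(a.sequence) == len(baseline):
            a.n_synonymous, a.n_nonsynonymous, a.has_internal_stop = count_nonsynonymous(
                a.sequence, baseline, ann
            )
        else:
            # still flag stops for functional genes with indel alleles
            off = ann.coding_frame_offset
            n = (len(a.sequence) - off) // 3 * 3
            aa = str(Seq(a.sequence[off:off + n]).translate())
            a.has_internal_stop = "*" in aa[:-1]
    return out


# ---------------------------------------------------------------------------
# RSS
# ---------------------------------------------------------------------------

def extract_rss_records(
    reference: Mapping[str, str],
    ann: GeneAnnotation,
    alleles: Sequence[AlleleCall] = (),
) -> list[RSSRecord]:
    """Reference RSS (heptamer / spacer / nonamer) per annotated side.

    The RSS is read strand-aware with the heptamer adjacent to the gene's
    coding flank.  Allele variants falling inside the RSS span (available
    when alleles were built in ``with_rss`` mode) are attached with
    RSS-local coordinates; the conserved-heptamer flag compares the
    reference heptamer with the canonical CACAGTG.
    """
    if not ann.rss:
        log.info("gene %s has no RSS annotation; skipped", ann.gene_name)
        return []
    records: list[RSSRecord] = []
    with_rss_total = sum(e - s for s, e in ann.intervals("with_rss"))
    for rss in ann.rss:
        raw = reference[ann.chromosome][rss.start: rss.end].upper()
        if ann.strand == "-":
            from .locus_model import revcomp

            raw = revcomp(raw)
        # in transcription orientation a 3' RSS starts with its heptamer,
        # a 5' RSS ends with it (heptamer abuts the coding flank)
        if rss.side == "3prime":
            heptamer = raw[:HEPTAMER_LEN]
            nonamer = raw[-NONAMER_LEN:]
        else:
            heptamer = raw[-HEPTAMER_LEN:]
            nonamer = raw[:NONAMER_LEN]
        rec = RSSRecord(
            gene_name=ann.gene_name,
            side=rss.side,
            heptamer=heptamer,
            spacer_length=rss.spacer_length,
            nonamer=nonamer,
            conserved_heptamer=heptamer == CANONICAL_HEPTAMER,
        )
        # locate the RSS span inside the with_rss transcription coordinates
        local_start = ann.genomic_to_local(
            rss.start if ann.strand == "+" else rss.end - 1, "with_rss"
        )
        assert local_start is not None
        span_len = rss.end - rss.start
        for allele in alleles:
            if allele.region_mode != "with_rss":
                continue
            for pos, ref, alt in allele.applied_variants:
                if local_start <= pos < local_start + span_len:
                    rec.variants.append((allele.allele_id, pos - local_start, ref, alt))
        records.append(rec)
    return records
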