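"""Seeded miniature receptor locus with ground-truth alleles.

Generates, with no external downloads, everything the pipeline consumes:
a reference contig carrying several V genes (leader + V exon + 3' RSS with
the canonical CACAGTG heptamer and a 23-bp spacer, some genes minus-strand),
an annotation table, a known-allele FASTA, a population panel, and a phased
VCF that encodes each sample haplotype's truth allele exactly.  The truth
table records every haplotype→allele assignment and the expected support,
allele-set category and population category, and serves as the end-to-end
oracle: collapsing the reconstructed haplotypes must reproduce it.

The default configuration emulates the study conditions at desk scale:
a multi-population diploid cohort (4 populations × 50 samples across four
super-populations), 6 V genes, 12 planted non-reference alleles covering
every classification and population category, and an operationally
indistinguishable gene pair (p-distance ≤ 0.02) carrying one planted shared
artifact mutation and one database-rescued shared mutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from .locus_model import (
    CANONICAL_HEPTAMER,
    CANONICAL_NONAMER,
    Exon,
    GeneAnnotation,
    KnownAllele,
    KnownAlleleDB,
    PopulationPanel,
    RSSInterval,
    revcomp,
    write_gene_annotation,
    write_known_db,
    write_population_panel,
)

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class AlleleSpec:
    """One planted truth allele: mutation set + target population frequencies."""

    truth_id: str
    mutations: tuple[tuple[int, str], ...]  # (position in complete coords, alt base)
    frequencies: dict[str, float]  # population -> haplotype frequency
    in_known_db: bool = False
    is_artifact: bool = False  # planted OI mis-mapping artifact


@dataclass
class GeneSpec:
    name: str
    strand: str = "+"
    alleles: list[AlleleSpec] = field(default_factory=list)
    #: extra known-DB records (mutation sets) not simulated in the cohort
    extra_db_alleles: list[tuple[tuple[int, str], ...]] = field(default_factory=list)
    #: gene whose sequence this gene is a near-copy of (OI pair injection)
    oi_copy_of: Optional[str] = None
    #: known-DB record for the reference allele written without its leader
    reference_db_partial: bool = False


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic locus; seeded and fully deterministic."""

    rng_seed: int = 0
    chromosome: str = "chrS"
    locus: str = "TRA"
    leader_len: int = 48
    v_exon_len: int = 288
    spacer_len: int = 23
    intergenic: int = 80
    #: population -> (super-population, number of diploid samples)
    populations: dict[str, tuple[str, int]] = field(
        default_factory=lambda: {
            "YRI": ("AFR", 50),
            "PEL": ("AMR", 50),
            "CHB": ("EAS", 50),
            "CEU": ("EUR", 50),
        }
    )
    inject_oi_pair: bool = True
    oi_divergence: int = 5  # substitutions between the OI pair references
    gene_plan: Optional[list[GeneSpec]] = None

    def __post_init__(self) -> None:
        if self.leader_len % 3 or self.v_exon_len % 3:
            raise ValueError("exon lengths must be codon multiples")
        for spec in self.plan():
            for a in spec.alleles:
                for pos, _ in a.mutations:
                    if not 0 <= pos < self.leader_len + self.v_exon_len:
                        raise ValueError(f"{a.truth_id}: mutation outside gene")
                for f in a.frequencies.values():
                    if not 0 <= f <= 1:
                        raise ValueError(f"{a.truth_id}: frequency outside [0,1]")

    def plan(self) -> list[GeneSpec]:
        if self.gene_plan is not None:
            return self.gene_plan
        return default_gene_plan(oi_pair=self.inject_oi_pair)


def default_gene_plan(oi_pair: bool = True) -> list[GeneSpec]:
    """Six V genes with 12 planted alleles covering all AS and population categories.

    Mutation alt bases are placeholders ("?") resolved against the seeded
    reference so that no allele introduces a stop codon.
    """
    q = "?"
    plan = [
        GeneSpec("TRAV1", "+", [
            AlleleSpec("TRAV1.t1", ((60, q),), {"YRI": 0.25, "PEL": 0.25, "CHB": 0.25, "CEU": 0.25},
                       in_known_db=True),
            AlleleSpec("TRAV1.t2", ((90, q),), {"YRI": 0.15}),
        ]),
        GeneSpec("TRAV2", "+", [
            AlleleSpec("TRAV2.t1", ((75, q),), {"YRI": 0.2, "PEL": 0.2, "CHB": 0.2, "CEU": 0.2}),
            AlleleSpec("TRAV2.t2", ((120, q),), {"YRI": 0.12, "PEL": 0.12}),
        ], reference_db_partial=True),
        GeneSpec("TRAV3", "+", [
            AlleleSpec("TRAV3.t1", ((66, q),), {"CEU": 0.12, "CHB": 0.10}),
            AlleleSpec("TRAV3.t2", ((150, q),), {"CHB": 0.06}),
        ]),
        GeneSpec("TRAV4", "-", [
            AlleleSpec("TRAV4.t1", ((81, q),), {"YRI": 0.3, "CEU": 0.2}, in_known_db=True),
            AlleleSpec("TRAV4.t2", ((96, q),), {"PEL": 0.25}),
        ]),
    ]
    if oi_pair:
        plan += [
            GeneSpec("TRAV5", "+", [
                AlleleSpec("TRAV5.art", ((105, q),), {"CEU": 0.08}, is_artifact=True),
                AlleleSpec("TRAV5.res", ((129, q), (201, q)), {"YRI": 0.10}),
            ], extra_db_alleles=[((129, q),)]),
            GeneSpec("TRAV6", "+", [
                AlleleSpec("TRAV6.art", ((105, q),), {"CEU": 0.08}, is_artifact=True),
                AlleleSpec("TRAV6.res", ((129, q), (210, q)), {"YRI": 0.10}),
            ], oi_copy_of="TRAV5"),
        ]
    else:
        plan += [
            GeneSpec("TRAV5", "+", [
                AlleleSpec("TRAV5.t1", ((105, q),), {"CEU": 0.08}),
                AlleleSpec("TRAV5.t2", ((129, q), (201, q)), {"YRI": 0.10}),
            ]),
            GeneSpec("TRAV6", "+", [
                AlleleSpec("TRAV6.t1", ((105, q),), {"CEU": 0.08}),
                AlleleSpec("TRAV6.t2", ((129, q), (210, q)), {"YRI": 0.10}),
            ]),
        ]
    return plan


@dataclass
class TruthAllele:
    gene_name: str
    truth_id: str
    sequence: str  # complete-region, transcription orientation
    mutations: tuple[tuple[int, str], ...]
    count: int
    expected_category: str  # AS1/AS2/AS3/discarded
    expected_pop_category: str  # ALL/AFR/AFR_SHARED/NON_AFR
    expect_filtered: bool
    counts_by_superpopulation: dict[str, int] = field(default_factory=dict)


@dataclass
class TruthSet:
    config: SimulationConfig
    reference: dict[str, str]
    annotations: list[GeneAnnotation]
    panel: PopulationPanel
    known_db: KnownAlleleDB
    gene_complete_refs: dict[str, str]
    #: (sample, phase, gene) -> truth_id ("ref" for the reference allele)
    assignments: dict[tuple[str, int, str], str]
    alleles: list[TruthAllele]

    def alleles_for(self, gene: str) -> list[TruthAllele]:
        return [a for a in self.alleles if a.gene_name == gene]


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_coding(rng: np.random.Generator, n_codons: int, start_codon: bool) -> str:
    codons = []
    if start_codon:
        codons.append("ATG")
        n_codons -= 1
    while len(codons) < n_codons + (1 if start_codon else 0):
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _has_internal_stop(seq: str) -> bool:
    aa = str(Seq(seq[: len(seq) // 3 * 3]).translate())
    return "*" in aa[:-1]


def _choose_alt(complete_ref: str, pos: int, *, also_valid_in: Sequence[str] = ()) -> str:
    """Deterministically pick an alt base at ``pos`` that creates no stop codon."""
    ref = complete_ref[pos]
    for base in _BASES:
        if base == ref:
            continue
        mutated = complete_ref[:pos] + base + complete_ref[pos + 1:]
        if _has_internal_stop(mutated):
            continue
        ok = True
        for other in also_valid_in:
            if other[pos] == base or _has_internal_stop(
                other[:pos] + base + other[pos + 1:]
            ):
                ok = False
                break
        if ok:
            return base
    raise RuntimeError(f"no stop-free alt base at position {pos}")


def _apply_mutations(complete_ref: str, mutations: Sequence[tuple[int, str]]) -> str:
    seq = list(complete_ref)
    for pos, alt in mutations:
        seq[pos] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_reference_and_annotation(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[GeneAnnotation], dict[str, str], list[GeneSpec]]:
    """Reference contig, annotations, per-gene complete sequences and resolved plan.

    Placeholder alt bases in the plan are resolved here (stop-free, and for
    OI-shared mutations identical and stop-free in both pair members).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    plan = [GeneSpec(g.name, g.strand,
                     [AlleleSpec(a.truth_id, a.mutations, dict(a.frequencies),
                                 a.in_known_db, a.is_artifact) for a in g.alleles],
                     [tuple(m) for m in g.extra_db_alleles],
                     g.oi_copy_of, g.reference_db_partial)
            for g in cfg.plan()]

    # complete (leader+V-exon) reference per gene
    complete: dict[str, str] = {}
    forbidden: dict[str, set[int]] = {
        g.name: {p for a in g.alleles for p, _ in a.mutations}
        | {p for m in g.extra_db_alleles for p, _ in m}
        for g in plan
    }
    for g in plan:
        if g.oi_copy_of:
            src = complete[g.oi_copy_of]
            seq = list(src)
            banned = forbidden[g.name] | forbidden[g.oi_copy_of]
            placed = 0
            while placed < cfg.oi_divergence:
                pos = int(rng.integers(0, len(seq)))
                if pos in banned:
                    continue
                alt = _BASES[int(rng.integers(0, 4))]
                if alt == seq[pos]:
                    continue
                cand = "".join(seq[:pos] + [alt] + seq[pos + 1:])
                if _has_internal_stop(cand):
                    continue
                seq[pos] = alt
                banned.add(pos)
                placed += 1
            complete[g.name] = "".join(seq)
        else:
            complete[g.name] = (
                _random_coding(rng, cfg.leader_len // 3, start_codon=True)
                + _random_coding(rng, cfg.v_exon_len // 3, start_codon=False)
            )

    # resolve placeholder alt bases
    for g in plan:
        partners = [complete[o.name] for o in plan
                    if o is not g and (o.oi_copy_of == g.name or g.oi_copy_of == o.name)]

        def resolve(mutations):
            out = []
            for pos, alt in mutations:
                if alt == "?":
                    alt = _choose_alt(complete[g.name], pos, also_valid_in=partners)
                out.append((pos, alt))
            return tuple(out)

        for a in g.alleles:
            a.mutations = resolve(a.mutations)
        g.extra_db_alleles = [resolve(m) for m in g.extra_db_alleles]

    # lay out the contig
    contig_parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    cursor = 0
    rss_len = 7 + cfg.spacer_len + 9
    for g in plan:
        cursor += cfg.intergenic
        spacer = "".join(rng.choice(list(_BASES), size=cfg.spacer_len))
        unit_t = complete[g.name] + CANONICAL_HEPTAMER + spacer + CANONICAL_NONAMER
        if g.strand == "+":
            genomic = unit_t
            leader = Exon("leader", cursor, cursor + cfg.leader_len)
            v_exon = Exon("v_exon", cursor + cfg.leader_len,
                          cursor + cfg.leader_len + cfg.v_exon_len)
            rss = RSSInterval(cursor + len(complete[g.name]),
                              cursor + len(unit_t), "3prime")
        else:
            genomic = revcomp(unit_t)
            rss = RSSInterval(cursor, cursor + rss_len, "3prime")
            v_exon = Exon("v_exon", cursor + rss_len, cursor + rss_len + cfg.v_exon_len)
            leader = Exon("leader", cursor + rss_len + cfg.v_exon_len,
                          cursor + len(unit_t))
        contig_parts.append("".join(rng.choice(list(_BASES), size=cfg.intergenic)))
        contig_parts.append(genomic)
        annotations.append(
            GeneAnnotation(g.name, cfg.locus, cfg.chromosome, g.strand, "V",
                           "functional", [leader, v_exon], [rss], 0)
        )
        cursor += len(unit_t)
    contig_parts.append("".join(rng.choice(list(_BASES), size=cfg.intergenic)))
    reference = {cfg.chromosome: "".join(contig_parts)}
    return reference, annotations, complete, plan


def build_known_db(plan: Sequence[GeneSpec], complete: Mapping[str, str],
                   leader_len: int) -> KnownAlleleDB:
    db = KnownAlleleDB()
    for g in plan:
        n = 1
        if g.reference_db_partial:
            db.add(KnownAllele(f"{g.name}*{n:02d}", complete[g.name][leader_len:],
                               has_leader=False, region_covered="v_exon_only"))
        else:
            db.add(KnownAllele(f"{g.name}*{n:02d}", complete[g.name]))
        for a in g.alleles:
            if a.in_known_db:
                n += 1
                db.add(KnownAllele(f"{g.name}*{n:02d}",
                                   _apply_mutations(complete[g.name], a.mutations)))
        for muts in g.extra_db_alleles:
            n += 1
            db.add(KnownAllele(f"{g.name}*{n:02d}",
                               _apply_mutations(complete[g.name], muts)))
    return db


def simulate_cohort(
    cfg: SimulationConfig,
    plan: Sequence[GeneSpec],
    complete: Mapping[str, str],
    db: KnownAlleleDB,
    leader_len: int,
) -> tuple[PopulationPanel, dict[tuple[str, int, str], str], list[TruthAllele]]:
    """Panel + per-haplotype truth assignments + realized truth-allele table.

    Each haplotype of each sample draws, per gene, an allele from the
    population's frequency vector (remainder mass goes to the reference
    allele).  Expected categories are computed from the *realized* counts by
    the truth logic itself, independently of the pipeline.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    entries: dict[str, tuple[str, str]] = {}
    for pop, (sup, n) in cfg.populations.items():
        for i in range(n):
            entries[f"{pop}{i:03d}"] = (pop, sup)
    panel = PopulationPanel(entries)

    assignments: dict[tuple[str, int, str], str] = {}
    counts: dict[tuple[str, str], int] = {}
    sup_counts: dict[tuple[str, str], dict[str, int]] = {}
    for g in plan:
        for sample, (pop, sup) in entries.items():
            freqs = [a.frequencies.get(pop, 0.0) for a in g.alleles]
            total = sum(freqs)
            if total > 1:
                warnings.warn(f"{g.name}/{pop}: frequencies sum to {total:.3f}; normalized")
                freqs = [f / total for f in freqs]
                total = 1.0
            probs = np.array(freqs + [1.0 - total])
            probs = probs / probs.sum()
            ids = [a.truth_id for a in g.alleles] + ["ref"]
            for phase in (0, 1):
                choice = ids[int(rng.choice(len(ids), p=probs))]
                assignments[(sample, phase, g.name)] = choice
                key = (g.name, choice)
                counts[key] = counts.get(key, 0) + 1
                sc = sup_counts.setdefault(key, {})
                sc[sup] = sc.get(sup, 0) + 1

    all_sups = set(panel.superpopulations)
    truth_alleles: list[TruthAllele] = []
    for g in plan:
        specs = {a.truth_id: a for a in g.alleles}
        for tid in list(specs) + ["ref"]:
            count = counts.get((g.name, tid), 0)
            if count == 0:
                continue
            muts = specs[tid].mutations if tid != "ref" else ()
            seq = _apply_mutations(complete[g.name], muts)
            known = _truth_known(seq, g.name, db, leader_len)
            if count < 4:
                cat = "discarded"
            elif known:
                cat = "AS1"
            elif count >= 19:
                cat = "AS2"
            else:
                cat = "AS3"
            present = {s for s, c in sup_counts[(g.name, tid)].items() if c >= 1}
            if present == all_sups:
                pop_cat = "ALL"
            elif "AFR" in present:
                pop_cat = "AFR" if present == {"AFR"} else "AFR_SHARED"
            else:
                pop_cat = "NON_AFR"
            truth_alleles.append(
                TruthAllele(g.name, tid, seq, tuple(muts), count, cat, pop_cat,
                            expect_filtered=(tid != "ref" and specs[tid].is_artifact),
                            counts_by_superpopulation=dict(sup_counts[(g.name, tid)]))
            )
    return panel, assignments, truth_alleles


def _truth_known(seq: str, gene: str, db: KnownAlleleDB, leader_len: int) -> bool:
    for rec in db.alleles_for(gene):
        if rec.has_leader and seq == rec.sequence:
            return True
        if not rec.has_leader and seq[leader_len:] == rec.sequence:
            return True
    return False


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def write_phased_vcf(
    truth: TruthSet,
    path: str | Path,
) -> int:
    """Emit a phased VCF (0|1-style GT) exactly encoding every truth haplotype.

    Gene-local complete-region mutation coordinates are converted to genomic
    positions (strand-aware, complemented for minus-strand genes).  Distinct
    alt bases at one genomic site become a multi-allelic record.  Returns the
    number of records written.
    """
    cfg = truth.config
    ann_by_gene = {a.gene_name: a for a in truth.annotations}
    plan = {g.name: g for g in _plan_from_truth(truth)}

    # genomic site table: pos -> {"ref": base, "alts": [..]}
    sites: dict[int, dict] = {}
    mut_site: dict[tuple[str, int, str], tuple[int, int]] = {}  # (gene,pos,alt)->(gpos, alt_idx)
    contig = truth.reference[cfg.chromosome]
    for gene, g in plan.items():
        ann = ann_by_gene[gene]
        total = sum(e - s for s, e in ann.intervals("complete"))
        start = ann.intervals("complete")[0][0]
        for a in g.alleles:
            for t_pos, alt in a.mutations:
                if ann.strand == "+":
                    gpos = start + t_pos
                    g_alt = alt
                else:
                    gpos = start + (total - 1 - t_pos)
                    g_alt = revcomp(alt)
                site = sites.setdefault(gpos, {"ref": contig[gpos], "alts": []})
                if g_alt not in site["alts"]:
                    site["alts"].append(g_alt)
                mut_site[(gene, t_pos, alt)] = (gpos, site["alts"].index(g_alt) + 1)

    # per-haplotype allele index at each site
    samples = truth.panel.samples
    gt: dict[int, dict[str, list[int]]] = {
        gpos: {s: [0, 0] for s in samples} for gpos in sites
    }
    for (sample, phase, gene), tid in truth.assignments.items():
        if tid == "ref":
            continue
        spec = next(a for a in plan[gene].alleles if a.truth_id == tid)
        for t_pos, alt in spec.mutations:
            gpos, idx = mut_site[(gene, t_pos, alt)]
            gt[gpos][sample][phase] = idx

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={cfg.chromosome},length={len(contig)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_samples(samples)
    n = 0
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for gpos in sorted(sites):
            site = sites[gpos]
            rec = vf.new_record(
                contig=cfg.chromosome, start=gpos, stop=gpos + 1,
                alleles=tuple([site["ref"]] + site["alts"]),
            )
            for s in samples:
                rec.samples[s]["GT"] = tuple(gt[gpos][s])
                rec.samples[s].phased = True
            vf.write(rec)
            n += 1
    return n


def _plan_from_truth(truth: TruthSet) -> list[GeneSpec]:
    return truth._resolved_plan  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# one-call fixture
# ---------------------------------------------------------------------------

def generate_truth_set(cfg: SimulationConfig) -> TruthSet:
    reference, annotations, complete, plan = generate_reference_and_annotation(cfg)
    db = build_known_db(plan, complete, cfg.leader_len)
    panel, assignments, truth_alleles = simulate_cohort(
        cfg, plan, complete, db, cfg.leader_len
    )
    ts = TruthSet(
        config=cfg,
        reference=reference,
        annotations=annotations,
        panel=panel,
        known_db=db,
        gene_complete_refs=complete,
        assignments=assignments,
        alleles=truth_alleles,
    )
    ts._resolved_plan = plan  # type: ignore[attr-defined]
    return ts


def generate_fixture(cfg: SimulationConfig, outdir: str | Path) -> TruthSet:
    """Write the full fixture (FASTA, TSVs, known DB, phased VCF, truth tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth_set(cfg)
    with open(outdir / "reference.fa", "w") as fh:
        for chrom, seq in truth.reference.items():
            fh.write(f">{chrom}\n{seq}\n")
    write_gene_annotation(truth.annotations, outdir / "annotation.tsv")
    write_population_panel(truth.panel, outdir / "panel.tsv")
    write_known_db(truth.known_db, outdir / "known_db.fa")
    write_phased_vcf(truth, outdir / "cohort.vcf")
    with open(outdir / "truth_alleles.tsv", "w") as fh:
        fh.write("gene\ttruth_id\tcount\texpected_category\texpected_pop_category\t"
                 "expect_filtered\tmutations\tsequence\n")
        for a in truth.alleles:
            muts = ",".join(f"{p}:{b}" for p, b in a.mutations)
            fh.write(f"{a.gene_name}\t{a.truth_id}\t{a.count}\t{a.expected_category}\t"
                     f"{a.expected_pop_category}\t{int(a.expect_filtered)}\t{muts}\t"
                     f"{a.sequence}\n")
    with open(outdir / "truth_assignments.tsv", "w") as fh:
        fh.write("sample\tphase\tgene\ttruth_id\n")
        for (sample, phase, gene), tid in sorted(truth.assignments.items()):
            fh.write(f"{sample}\t{phase}\t{gene}\t{tid}\n")
    return truth
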