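"""End-to-end orchestration, allele-set comparison and summary tables.

``run_pipeline`` chains the stages — haplotype reconstruction, allele
collapsing and annotation, curation, population annotation, locus-level
PCA/Fst — and writes plain-text outputs (TSV/FASTA/newick) plus a manifest
with a config hash, so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import allele_caller, curation, haplotyper, locus_model, popgen

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    reference: str
    annotation: str
    panel: str
    known_db: str
    outdir: str
    min_support: int = 4
    frequent_support: int = 19
    oi_branch: float = 0.02
    oi_branch_rule: str = "each_branch"
    presence_threshold: int = 4
    region_mode: str = "complete"
    snps_only: bool = False
    fst_estimator: str = "hudson"
    pca_scale: bool = True
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_support <= 0 or self.frequent_support <= 0:
            raise ValueError("support thresholds must be positive")
        if self.min_support > self.frequent_support:
            raise ValueError("min_support must not exceed frequent_support")
        if self.oi_branch <= 0 or self.presence_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    outdir: Path
    alleles: list[allele_caller.AlleleCall]
    removed: list[curation.FilterDecision]
    oi_groups: list[curation.OIGroup]
    distributions: dict[str, popgen.PopulationDistribution]
    manifest: dict


@dataclass
class AlleleSetComparison:
    """Sequence-level overlap between two allele sets (per gene and aggregate)."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_shared: int
    a_only: list[tuple[str, str]] = field(default_factory=list)
    b_only: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_shared <= min(self.n_a, self.n_b)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "status": "INCOMPLETE"}
    manifest_path = outdir / "manifest.json"
    try:
        result = _run_stages(cfg, outdir, manifest)
    except Exception:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["status"] = "COMPLETE"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    return result


def _run_stages(cfg: PipelineConfig, outdir: Path, manifest: dict) -> PipelineResult:
    annotations = locus_model.load_gene_annotation(cfg.annotation)
    panel = locus_model.load_population_panel(cfg.panel)
    db = locus_model.load_known_db(cfg.known_db)
    reference = locus_model.load_reference(cfg.reference)
    ann_by_gene = {a.gene_name: a for a in annotations}
    ref_seqs = {
        a.gene_name: locus_model.extract_gene_reference(reference, a, cfg.region_mode)
        for a in annotations
    }

    all_alleles: list[allele_caller.AlleleCall] = []
    hap_counts: dict[str, int] = {}
    for ann in annotations:
        haps = haplotyper.reconstruct_gene_haplotypes(
            cfg.vcf, reference, ann, panel, cfg.region_mode, snps_only=cfg.snps_only
        )
        hap_counts[ann.gene_name] = len(haps)
        calls = allele_caller.collapse_haplotypes(haps)
        calls = allele_caller.annotate_alleles(
            calls, db, ann, ref_seqs[ann.gene_name],
            min_support=cfg.min_support, frequent_support=cfg.frequent_support,
        )
        all_alleles.extend(calls)

    retained = [a for a in all_alleles if a.category != "discarded"]
    kept, removed, oi_groups = curation.curate_alleles(
        retained, ann_by_gene, db, ref_seqs,
        oi_threshold=cfg.oi_branch, branch_rule=cfg.oi_branch_rule,
    )

    distributions = {
        a.allele_id: popgen.annotate_population(a, panel, cfg.presence_threshold)
        for a in all_alleles
    }

    _write_allele_outputs(outdir, cfg, all_alleles, kept, removed, distributions, panel)
    _write_rss(outdir, reference, ann_by_gene, all_alleles)
    _write_trees(outdir, ann_by_gene, ref_seqs)
    _write_popgen(outdir, cfg, annotations, panel)

    manifest.update(
        {
            "haplotype_counts": hap_counts,
            "n_samples": len(panel),
            "n_alleles_total": len(all_alleles),
            "n_alleles_kept": len(kept),
            "n_alleles_removed": len(removed),
            "oi_groups": [sorted(g.member_genes) for g in oi_groups],
            "genes": locus_model.manifest_report(
                annotations, (a.gene_name for a in all_alleles)
            ),
        }
    )
    return PipelineResult(outdir, all_alleles, removed, oi_groups, distributions, manifest)


def _write_allele_outputs(outdir, cfg, all_alleles, kept, removed, distributions, panel):
    kept_ids = {id(a) for a in kept}
    fasta_dir = outdir / "alleles"
    fasta_dir.mkdir(exist_ok=True)
    by_gene: dict[str, list] = {}
    for a in all_alleles:
        by_gene.setdefault(a.gene_name, []).append(a)
    header = (
        "gene\tallele_id\thaplotype_count\tcategory\tfilter_reason\tknown_match\t"
        "match_mode\tnearest_known\tn_mutations\tn_mutations_v_exon\t"
        "n_synonymous\tn_nonsynonymous\tpop_category\tmutations\n"
    )
    with open(outdir / "alleles.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        fh.write(header)
        for gene in sorted(by_gene):
            with open(fasta_dir / f"{gene}.fasta", "w") as fa:
                for a in by_gene[gene]:
                    km = a.known_match.allele_id if a.known_match else ""
                    fa.write(
                        f">{a.allele_id}|count={a.haplotype_count}|"
                        f"category={a.category}|known={km or 'NA'}\n{a.sequence}\n"
                    )
                    muts = ",".join(
                        f"{p}{r}>{alt}" for p, r, alt in a.mutations_vs_nearest_known
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene,
                                a.allele_id,
                                str(a.haplotype_count),
                                a.category,
                                a.filter_reason or "",
                                km,
                                a.known_match.match_mode if a.known_match else "",
                                a.nearest_known or "",
                                str(len(a.mutations_vs_nearest_known)),
                                str(a.mutation_count_v_exon),
                                str(a.n_synonymous),
                                str(a.n_nonsynonymous),
                                distributions[a.allele_id].category,
                                muts,
                            ]
                        )
                        + "\n"
                    )
    with open(outdir / "curation_report.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        fh.write("allele_id\tgene\tfilter\treason\tevidence\n")
        for d in removed:
            fh.write(f"{d.allele_id}\t{d.gene_name}\t{d.filter}\t{d.reason}\t{d.evidence}\n")
    pops = panel.populations
    sups = panel.superpopulations
    with open(outdir / "population_distribution.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        fh.write("allele_id\tcategory\t" + "\t".join(pops + sups) + "\n")
        for a in all_alleles:
            d = distributions[a.allele_id]
            row = [str(d.counts_by_population[p]) for p in pops]
            row += [str(d.counts_by_superpopulation[s]) for s in sups]
            fh.write(f"{a.allele_id}\t{d.category}\t" + "\t".join(row) + "\n")


def _write_rss(outdir, reference, ann_by_gene, all_alleles):
    with open(outdir / "rss.tsv", "w") as fh:
        fh.write("gene\tside\theptamer\tspacer_length\tnonamer\tconserved_heptamer\tvariants\n")
        for gene in sorted(ann_by_gene):
            ann = ann_by_gene[gene]
            if not ann.rss:
                continue
            for rec in allele_caller.extract_rss_records(reference, ann, []):
                fh.write(
                    f"{gene}\t{rec.side}\t{rec.heptamer}\t{rec.spacer_length}\t"
                    f"{rec.nonamer}\t{int(rec.conserved_heptamer)}\t\n"
                )


def _write_trees(outdir, ann_by_gene, ref_seqs):
    v_by_locus: dict[str, dict[str, str]] = {}
    for gene, ann in ann_by_gene.items():
        if ann.segment_type == "V":
            v_by_locus.setdefault(ann.locus, {})[gene] = ref_seqs[gene]
    for locus, seqs in sorted(v_by_locus.items()):
        if len(seqs) < 3:
            continue
        dm = curation.pairwise_gene_distances(seqs)
        tree = curation.build_nj_tree(dm)
        with open(outdir / f"vgene_tree_{locus}.nwk", "w") as fh:
            fh.write(str(tree).strip() + "\n")
        with open(outdir / f"vgene_alignment_{locus}.fasta", "w") as fh:
            for gene in dm.labels:
                fh.write(f">{gene}\n{seqs[gene]}\n")


def _write_popgen(outdir, cfg, annotations, panel):
    chroms = {a.chromosome for a in annotations}
    for chrom in sorted(chroms):
        anns = [a for a in annotations if a.chromosome == chrom]
        start = min(a.span("complete")[0] for a in anns)
        end = max(a.span("complete")[1] for a in anns)
        try:
            m = popgen.build_genotype_matrix(cfg.vcf, chrom, start, end, panel)
        except ValueError as exc:
            log.warning("popgen skipped for %s: %s", chrom, exc)
            continue
        coords, evr = popgen.run_pca(m, n_components=min(10, len(panel) - 1),
                                     scale=cfg.pca_scale)
        with open(outdir / f"pca_{chrom}.tsv", "w") as fh:
            fh.write("sample\t" + "\t".join(f"PC{i+1}" for i in range(coords.shape[1])) + "\n")
            for s, row in zip(m.samples, coords):
                fh.write(s + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
            fh.write("#explained_variance_ratio\t"
                     + "\t".join(f"{x:.6g}" for x in evr) + "\n")
        if len(panel.populations) >= 2:
            fst = popgen.pairwise_fst(m, panel, cfg.fst_estimator)
            with open(outdir / f"fst_{chrom}.tsv", "w") as fh:
                fh.write(f"# estimator={fst.estimator}\n")
                fh.write("population\t" + "\t".join(fst.populations) + "\n")
                for i, p in enumerate(fst.populations):
                    fh.write(p + "\t" + "\t".join(f"{x:.6g}" for x in fst.values[i]) + "\n")
            if len(fst.populations) >= 3:
                with open(outdir / f"fst_tree_{chrom}.nwk", "w") as fh:
                    fh.write(popgen.fst_cladogram(fst) + "\n")


# ---------------------------------------------------------------------------
# comparison and summaries
# ---------------------------------------------------------------------------

def compare_allele_sets(
    set_a: dict[str, list[str]],
    set_b: dict[str, list[str]],
    *,
    name_a: str = "A",
    name_b: str = "B",
) -> AlleleSetComparison:
    """Overlap of two gene→sequences allele sets by exact sequence equality."""
    pairs_a = {(g, s) for g, seqs in set_a.items() for s in seqs}
    pairs_b = {(g, s) for g, seqs in set_b.items() for s in seqs}
    shared = pairs_a & pairs_b
    return AlleleSetComparison(
        set_a=name_a,
        set_b=name_b,
        n_a=len(pairs_a),
        n_b=len(pairs_b),
        n_shared=len(shared),
        a_only=sorted(pairs_a - pairs_b),
        b_only=sorted(pairs_b - pairs_a),
    )


def load_allele_fasta(path: str | Path) -> dict[str, list[str]]:
    """Read a per-gene allele FASTA written by the pipeline into gene→sequences."""
    from Bio import SeqIO

    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        allele_id = rec.id.split("|")[0]
        gene = allele_id.rsplit("_", 1)[0]
        out.setdefault(gene, []).append(str(rec.seq).upper())
    return out


def summarize_tables(
    alleles: Sequence[allele_caller.AlleleCall],
    ann_by_gene: dict[str, locus_model.GeneAnnotation],
) -> tuple[dict, dict]:
    """Per (locus, segment type) AS counts and mutation-count histograms.

    Returns (category_summary, mutation_histogram): the first maps
    (locus, segment_type) to AS1/AS2/AS3/total counts; the second bins the
    number of mutating positions vs the nearest known allele (0,1,2,3+)
    for the complete sequence and the V exon only.
    """
    cat_summary: dict[tuple[str, str], dict[str, int]] = {}
    hist = {
        "complete": {"0": 0, "1": 0, "2": 0, "3+": 0},
        "v_exon_only": {"0": 0, "1": 0, "2": 0, "3+": 0},
    }
    for a in alleles:
        if a.category in ("discarded", "filtered", "unclassified"):
            continue
        ann = ann_by_gene[a.gene_name]
        key = (ann.locus, ann.segment_type)
        row = cat_summary.setdefault(key, {"AS1": 0, "AS2": 0, "AS3": 0, "total": 0})
        row[a.category] += 1
        row["total"] += 1
        for mode, n in (
            ("complete", len(a.mutations_vs_nearest_known)),
            ("v_exon_only", a.mutation_count_v_exon),
        ):
            hist[mode][str(n) if n < 3 else "3+"] += 1
    return cat_summary, hist
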