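"""Domain types and I/O for receptor-gene annotations, panels and allele databases.

All coordinate and strand conventions are normalized here: files use 1-based
inclusive genomic coordinates (the usual convention of annotation tables),
while every in-memory interval is 0-based half-open.  Minus-strand genes are
stored with exons in genomic order; transcription order is derived on demand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

LOCI = ("TRA", "TRB", "TRG", "TRD")
SEGMENT_TYPES = ("V", "D", "J", "C")
FUNCTIONALITIES = ("functional", "ORF", "pseudogene")
SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
REGION_MODES = ("complete", "v_exon_only", "leader", "with_rss")

#: canonical recombination-signal heptamer on the coding-flank convention
CANONICAL_HEPTAMER = "CACAGTG"
#: canonical nonamer (consensus), used by the simulator
CANONICAL_NONAMER = "ACAAAAACC"

HEPTAMER_LEN = 7
NONAMER_LEN = 9
SPACER_LENGTHS = (12, 23)
#: legal total RSS spans: heptamer + spacer + nonamer
RSS_SPANS = tuple(HEPTAMER_LEN + s + NONAMER_LEN for s in SPACER_LENGTHS)


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation input."""


class PanelError(ValueError):
    """Malformed or inconsistent population panel input."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase preserved)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Exon:
    """One exon interval, 0-based half-open genomic coordinates."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"empty exon interval {self.label}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RSSInterval:
    """Full recombination-signal-sequence span (heptamer+spacer+nonamer)."""

    start: int
    end: int
    side: str  # "5prime" or "3prime", relative to the gene in transcription orientation

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise AnnotationError(f"bad RSS side {self.side!r}")
        if self.end - self.start not in RSS_SPANS:
            raise AnnotationError(
                f"RSS span {self.end - self.start} bp is not heptamer+{SPACER_LENGTHS}+nonamer"
            )

    @property
    def spacer_length(self) -> int:
        return (self.end - self.start) - HEPTAMER_LEN - NONAMER_LEN


@dataclass
class GeneAnnotation:
    """Genomic structure of one receptor gene (V, D, J or C segment).

    Exons are kept sorted by genomic position regardless of strand; use
    :meth:`intervals` / :meth:`transcription_exons` for strand-aware access.
    ``coding_frame_offset`` is the offset (0-2) of the first complete codon
    within the spliced complete sequence.
    """

    gene_name: str
    locus: str
    chromosome: str
    strand: str
    segment_type: str
    functionality: str
    exons: list[Exon]
    rss: list[RSSInterval] = field(default_factory=list)
    coding_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AnnotationError(f"{self.gene_name}: unknown locus {self.locus!r}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_name}: strand must be '+' or '-'")
        if self.segment_type not in SEGMENT_TYPES:
            raise AnnotationError(f"{self.gene_name}: unknown segment type {self.segment_type!r}")
        if self.functionality not in FUNCTIONALITIES:
            raise AnnotationError(f"{self.gene_name}: unknown functionality {self.functionality!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_name}: gene has no exons")
        if not 0 <= self.coding_frame_offset <= 2:
            raise AnnotationError(f"{self.gene_name}: coding_frame_offset must be 0-2")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.gene_name}: overlapping exons {a.label} and {b.label}"
                )

    # -- interval selection -------------------------------------------------

    def exon_by_label(self, label: str) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise AnnotationError(f"{self.gene_name}: no exon labelled {label!r}")

    @property
    def has_leader(self) -> bool:
        return any(e.label == "leader" for e in self.exons)

    @property
    def leader_length(self) -> int:
        return self.exon_by_label("leader").length if self.has_leader else 0

    def intervals(self, region_mode: str = "complete") -> list[tuple[int, int]]:
        """Genomic intervals (sorted by start) selected by ``region_mode``."""
        if region_mode not in REGION_MODES:
            raise AnnotationError(f"unknown region mode {region_mode!r}")
        if region_mode == "leader":
            return [(self.exon_by_label("leader").start, self.exon_by_label("leader").end)]
        if region_mode == "v_exon_only":
            if self.segment_type != "V":
                raise AnnotationError(
                    f"{self.gene_name}: v_exon_only undefined for {self.segment_type} gene"
                )
            e = self.exon_by_label("v_exon")
            return [(e.start, e.end)]
        ivals = [(e.start, e.end) for e in self.exons]
        if region_mode == "with_rss":
            ivals += [(r.start, r.end) for r in self.rss]
        return sorted(ivals)

    def span(self, region_mode: str = "complete") -> tuple[int, int]:
        ivals = self.intervals(region_mode)
        return ivals[0][0], ivals[-1][1]

    def transcription_exons(self) -> list[Exon]:
        """Exons in transcription (5'→3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_to_local(self, gpos: int, region_mode: str = "complete") -> Optional[int]:
        """Map a genomic position to a 0-based transcription-order coordinate.

        Returns None when the position falls outside the selected intervals.
        """
        ivals = self.intervals(region_mode)
        off = 0
        splice = None
        for s, e in ivals:
            if s <= gpos < e:
                splice = off + (gpos - s)
                break
            off += e - s
        if splice is None:
            return None
        total = sum(e - s for s, e in ivals)
        return splice if self.strand == "+" else total - 1 - splice


@dataclass(frozen=True)
class KnownAllele:
    """One database (IMGT-style) allele record."""

    allele_id: str  # e.g. TRAV1*01
    sequence: str
    has_leader: bool = True
    region_covered: str = "complete"  # complete | v_exon_only | partial_other

    @property
    def gene_name(self) -> str:
        return self.allele_id.split("*")[0]

    @property
    def number(self) -> int:
        return int(self.allele_id.split("*")[1])


@dataclass
class KnownAlleleDB:
    """Known-allele database keyed by gene name."""

    records: dict[str, list[KnownAllele]] = field(default_factory=dict)

    def add(self, allele: KnownAllele) -> None:
        recs = self.records.setdefault(allele.gene_name, [])
        if any(r.allele_id == allele.allele_id for r in recs):
            raise ValueError(f"duplicate allele id {allele.allele_id}")
        if set(allele.sequence) - set("ACGT"):
            raise ValueError(f"{allele.allele_id}: sequence contains non-ACGT characters")
        recs.append(allele)

    def alleles_for(self, gene_name: str) -> list[KnownAllele]:
        return self.records.get(gene_name, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.records.values())


@dataclass
class PopulationPanel:
    """Sample → (population, super-population) mapping."""

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        pop2super: dict[str, str] = {}
        for sample, (pop, sup) in self.entries.items():
            if sup not in SUPERPOPULATIONS:
                raise PanelError(f"sample {sample}: unknown super-population code {sup!r}")
            if pop2super.setdefault(pop, sup) != sup:
                raise PanelError(f"population {pop} mapped to multiple super-populations")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    @property
    def populations(self) -> list[str]:
        return sorted({p for p, _ in self.entries.values()})

    @property
    def superpopulations(self) -> list[str]:
        return sorted({s for _, s in self.entries.values()})

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def superpopulation_of(self, sample: str) -> str:
        return self.entries[sample][1]

    def superpopulation_of_population(self, pop: str) -> str:
        for p, s in self.entries.values():
            if p == pop:
                return s
        raise KeyError(pop)

    def counts_by_population(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop, _ in self.entries.values():
            out[pop] = out.get(pop, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = (
    "gene_name",
    "locus",
    "chromosome",
    "strand",
    "segment_type",
    "functionality",
    "features",
)


def _parse_feature_token(token: str, lineno: int) -> tuple[str, int, int]:
    try:
        label, span = token.split(":")
        lo, hi = span.split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: cannot parse feature token {token!r}") from exc
    if start1 < 1 or end1 < start1:
        raise AnnotationError(f"line {lineno}: bad interval in token {token!r}")
    # 1-based inclusive -> 0-based half-open
    return label.strip(), start1 - 1, end1


def load_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the tab-separated annotation dialect.

    Columns: gene_name, locus, chromosome, strand, segment_type, functionality,
    features[, coding_frame_offset].  ``features`` is a comma-separated list of
    ``label:start-end`` tokens with 1-based inclusive genomic coordinates; RSS
    spans use labels ``rss_5prime`` / ``rss_3prime`` and must be 28 or 39 bp.
    """
    path = Path(path)
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_ANNOT_COLUMNS)] != list(_ANNOT_COLUMNS):
            raise AnnotationError(f"{path}: unexpected header {header!r}")
        has_frame = len(header) > len(_ANNOT_COLUMNS) and header[7] == "coding_frame_offset"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(_ANNOT_COLUMNS):
                raise AnnotationError(f"line {lineno}: expected ≥7 columns, got {len(parts)}")
            name, locus, chrom, strand, seg, func, feats = parts[:7]
            if name in seen:
                raise AnnotationError(f"line {lineno}: duplicate gene name {name}")
            seen.add(name)
            exons: list[Exon] = []
            rss: list[RSSInterval] = []
            for token in feats.split(","):
                label, start, end = _parse_feature_token(token.strip(), lineno)
                if label.startswith("rss_"):
                    rss.append(RSSInterval(start, end, side=label[len("rss_"):]))
                else:
                    exons.append(Exon(label, start, end))
            frame = int(parts[7]) if has_frame and len(parts) > 7 and parts[7] else 0
            annotations.append(
                GeneAnnotation(name, locus, chrom, strand, seg, func, exons, rss, frame)
            )
    return annotations


def write_gene_annotation(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the dialect read by :func:`load_gene_annotation`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\tcoding_frame_offset\n")
        for ann in annotations:
            tokens = [f"{e.label}:{e.start + 1}-{e.end}" for e in ann.exons]
            tokens += [f"rss_{r.side}:{r.start + 1}-{r.end}" for r in ann.rss]
            fh.write(
                "\t".join(
                    [
                        ann.gene_name,
                        ann.locus,
                        ann.chromosome,
                        ann.strand,
                        ann.segment_type,
                        ann.functionality,
                        ",".join(tokens),
                        str(ann.coding_frame_offset),
                    ]
                )
                + "\n"
            )


def load_population_panel(path: str | Path) -> PopulationPanel:
    """Read a sample panel TSV with columns sample, population, super_population."""
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample", "population", "super_population"]:
            raise PanelError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            sample, pop, sup = line.split("\t")[:3]
            if sample in entries:
                if entries[sample] != (pop, sup):
                    raise PanelError(
                        f"line {lineno}: sample {sample} listed twice with conflicting populations"
                    )
                warnings.warn(f"panel: duplicate consistent row for sample {sample}")
                continue
            entries[sample] = (pop, sup)
    return PopulationPanel(entries)


def write_population_panel(panel: PopulationPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tsuper_population\n")
        for sample, (pop, sup) in panel.entries.items():
            fh.write(f"{sample}\t{pop}\t{sup}\n")


def load_known_db(path: str | Path) -> KnownAlleleDB:
    """Read a known-allele FASTA.

    Headers look like ``>TRAV1*01`` with an optional ``partial`` token marking
    records lacking the leader (region_covered = v_exon_only).
    """
    db = KnownAlleleDB()
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = (rec.id + " " + rec.description[len(rec.id):]).split()
        allele_id = tokens[0]
        partial = "partial" in tokens[1:]
        db.add(
            KnownAllele(
                allele_id=allele_id,
                sequence=str(rec.seq).upper(),
                has_leader=not partial,
                region_covered="v_exon_only" if partial else "complete",
            )
        )
    return db


def write_known_db(db: KnownAlleleDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(db.records):
            for rec in sorted(db.records[gene], key=lambda r: r.number):
                suffix = " partial" if not rec.has_leader else ""
                fh.write(f">{rec.allele_id}{suffix}\n{rec.sequence}\n")


def load_reference(path: str | Path) -> dict[str, str]:
    """Load a reference FASTA into a chrom → uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_gene_reference(
    reference: Mapping[str, str], ann: GeneAnnotation, region_mode: str = "complete"
) -> str:
    """Spliced reference sequence of a gene in transcription orientation.

    Exons (and, in ``with_rss`` mode, the RSS spans) are concatenated in
    genomic order and reverse-complemented for minus-strand genes, so the
    result always reads 5'→3' in the transcription direction.
    """
    if ann.chromosome not in reference:
        raise KeyError(f"chromosome {ann.chromosome} absent from reference")
    contig = reference[ann.chromosome]
    pieces = []
    for start, end in ann.intervals(region_mode):
        if end > len(contig):
            raise AnnotationError(
                f"{ann.gene_name}: interval {start}-{end} outside contig {ann.chromosome}"
            )
        pieces.append(contig[start:end])
    seq = "".join(pieces).upper()
    return revcomp(seq) if ann.strand == "-" else seq


def manifest_report(
    annotations: Sequence[GeneAnnotation], called_genes: Iterable[str]
) -> dict[str, list[str]]:
    """Annotated vs called gene manifest (assembly-absent genes simply never appear)."""
    annotated = [a.gene_name for a in annotations]
    called = set(called_genes)
    return {
        "annotated": annotated,
        "called": sorted(called),
        "annotated_not_called": [g for g in annotated if g not in called],
    }
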