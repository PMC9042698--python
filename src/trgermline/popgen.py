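"""Population annotation of alleles and locus-level diversity summaries.

Alleles get per-(super)population haplotype counts and one of four
categories — ALL (present in every super-population of the panel), AFR
(Africans only), AFR_SHARED (Africans plus some but not all others) and
NON_AFR (no African support).  Locus-level structure is summarized by a
genotype PCA over the biallelic SNPs of the locus and by pairwise Fst
between populations (Hudson ratio-of-averages by default, Weir–Cockerham as
an alternative), visualized as a neighbor-joining cladogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .allele_caller import AlleleCall
from .curation import DistanceMatrixT, build_nj_tree
from .haplotyper import PhasedVariantRecord, _iter_records
from .locus_model import PopulationPanel

log = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 4


@dataclass
class PopulationDistribution:
    """Per-allele haplotype counts by (super-)population plus category."""

    allele_id: str
    counts_by_population: dict[str, int]
    counts_by_superpopulation: dict[str, int]
    presence_by_population: dict[str, bool]
    category: str

    def total(self) -> int:
        return sum(self.counts_by_population.values())


@dataclass
class LocusGenotypeMatrix:
    """Samples × biallelic sites matrix of alt-allele dosages (0/1/2)."""

    samples: list[str]
    sites: list[tuple[int, str, str]]  # (1-based position, ref, alt)
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.int8)
        if d.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage matrix shape mismatch")
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in {0,1,2}")
        self.dosages = d


@dataclass
class FstMatrix:
    """Pairwise Fst between populations; values clamped to [0,1], raw kept."""

    populations: list[str]
    values: np.ndarray
    raw_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    estimator: str = "hudson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.raw_values is None:
            self.raw_values = v.copy()
        clamped = np.clip(v, 0.0, 1.0)
        if not np.allclose(clamped, v):
            log.info("negative/out-of-range Fst values clamped (raw values retained)")
        np.fill_diagonal(clamped, 0.0)
        self.values = clamped


def annotate_population(
    allele: AlleleCall,
    panel: PopulationPanel,
    presence_threshold: int = PRESENCE_THRESHOLD,
    *,
    strict: bool = True,
) -> PopulationDistribution:
    """Aggregate an allele's supporting haplotypes by (super-)population.

    Category assignment uses ≥1 supporting haplotype per super-population
    (so counts always sum to the allele's support); the per-population
    boolean presence flags use the separate ``presence_threshold`` (default
    4 haplotypes, the figure convention).
    """
    pops = {p: 0 for p in panel.populations}
    sups = {s: 0 for s in panel.superpopulations}
    for sample, _phase in allele.supporting_haplotypes:
        if sample not in panel.entries:
            if strict:
                raise KeyError(f"sample {sample} not in population panel")
            log.warning("sample %s not in panel; haplotype excluded", sample)
            continue
        pop, sup = panel.entries[sample]
        pops[pop] += 1
        sups[sup] += 1
    present = {s for s, c in sups.items() if c >= 1}
    all_sups = set(panel.superpopulations)
    if present == all_sups:
        category = "ALL"
    elif "AFR" in present:
        category = "AFR" if present == {"AFR"} else "AFR_SHARED"
    else:
        category = "NON_AFR"
    return PopulationDistribution(
        allele_id=allele.allele_id,
        counts_by_population=pops,
        counts_by_superpopulation=sups,
        presence_by_population={p: c >= presence_threshold for p, c in pops.items()},
        category=category,
    )


def build_genotype_matrix(
    vcf: str | Path | Sequence[PhasedVariantRecord],
    chromosome: str,
    start: int,
    end: int,
    panel: PopulationPanel,
) -> LocusGenotypeMatrix:
    """Biallelic-SNP dosage matrix over a locus interval (0-based half-open).

    Multi-allelic and indel records are dropped; sites monomorphic in the
    cohort are removed.
    """
    samples = panel.samples
    sites: list[tuple[int, str, str]] = []
    columns: list[np.ndarray] = []
    records = (
        _iter_records(vcf, chromosome, "error")
        if isinstance(vcf, (str, Path))
        else vcf
    )
    for rec in records:
        if rec.chromosome != chromosome or not (start <= rec.start < end):
            continue
        if len(rec.alt_alleles) != 1 or len(rec.ref_allele) != 1 or len(rec.alt_alleles[0]) != 1:
            continue
        col = np.array(
            [sum(rec.genotypes.get(s, (0, 0))) for s in samples], dtype=np.int8
        )
        if col.min() == col.max():  # monomorphic
            continue
        sites.append((rec.position, rec.ref_allele, rec.alt_alleles[0]))
        columns.append(col)
    if not sites:
        raise ValueError(f"no segregating biallelic SNPs in {chromosome}:{start}-{end}")
    return LocusGenotypeMatrix(
        samples=list(samples),
        sites=sites,
        dosages=np.column_stack(columns),
    )


def run_pca(
    m: LocusGenotypeMatrix,
    n_components: int = 10,
    *,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA: (sample coordinates, explained variance ratios).

    Columns are mean-centered; with ``scale`` they are divided by the
    binomial standard deviation sqrt(p(1-p)) of the site's allele frequency
    (the usual genotype-PCA normalization).  Components are ordered by
    decreasing eigenvalue with the sign fixed so the largest-magnitude
    loading of each component is positive.
    """
    X = m.dosages.astype(float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs ≥2 samples and ≥1 site")
    freq = X.mean(axis=0) / 2.0
    Xc = X - X.mean(axis=0)
    if scale:
        sd = np.sqrt(freq * (1 - freq))
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        log.warning("n_components %d > rank %d; truncated", n_components, rank)
        n_components = rank
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * S[:n_components]
    total_var = (S**2).sum()
    evr = (S[:n_components] ** 2) / total_var if total_var > 0 else S[:n_components] * 0
    return coords, evr


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def hudson_fst_components(
    ac1: np.ndarray, n1: np.ndarray, ac2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator and denominator of the Hudson Fst estimator.

    ``ac`` are alt-allele counts, ``n`` total allele counts per site.
    num = (p1-p2)^2 − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1);
    den = p1(1−p2) + p2(1−p1).
    """
    p1 = ac1 / n1
    p2 = ac2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def weir_cockerham_fst_components(
    ac1: np.ndarray, n1: np.ndarray, ac2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site a and a+b+c variance components of Weir–Cockerham theta (2 pops).

    Allele-count based form (haploid-allele pools per population).
    """
    r = 2.0
    n1h, n2h = n1 / 2.0, n2 / 2.0  # diploid sample sizes
    p1, p2 = ac1 / n1, ac2 / n2
    nbar = (n1h + n2h) / r
    nc = (n1h + n2h - (n1h**2 + n2h**2) / (n1h + n2h)) / (r - 1)
    pbar = (n1h * p1 + n2h * p2) / (n1h + n2h)
    s2 = (n1h * (p1 - pbar) ** 2 + n2h * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    # without genotype data, assume HWE heterozygosity
    hbar = (n1h * 2 * p1 * (1 - p1) + n2h * 2 * p2 * (1 - p2)) / (n1h + n2h)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def pairwise_fst(
    m: LocusGenotypeMatrix,
    panel: PopulationPanel,
    estimator: str = "hudson",
) -> FstMatrix:
    """Pairwise Fst between all panel populations (ratio of averages across sites)."""
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError("estimator must be 'hudson' or 'weir_cockerham'")
    pops = panel.populations
    idx: dict[str, np.ndarray] = {}
    for pop in list(pops):
        rows = [i for i, s in enumerate(m.samples) if panel.population_of(s) == pop]
        if not rows:
            log.warning("population %s has no samples in matrix; excluded", pop)
            pops = [p for p in pops if p != pop]
            continue
        idx[pop] = np.array(rows)
    k = len(pops)
    fst = np.zeros((k, k))
    comp = hudson_fst_components if estimator == "hudson" else weir_cockerham_fst_components
    for i in range(k):
        for j in range(i + 1, k):
            d1 = m.dosages[idx[pops[i]]]
            d2 = m.dosages[idx[pops[j]]]
            ac1, n1 = d1.sum(axis=0).astype(float), np.full(d1.shape[1], 2.0 * d1.shape[0])
            ac2, n2 = d2.sum(axis=0).astype(float), np.full(d2.shape[1], 2.0 * d2.shape[0])
            num, den = comp(ac1, n1, ac2, n2)
            keep = den > 0
            fst[i, j] = fst[j, i] = (
                num[keep].sum() / den[keep].sum() if keep.any() else 0.0
            )
    return FstMatrix(populations=list(pops), values=fst, raw_values=fst.copy(),
                     estimator=estimator)


def fst_cladogram(fst: FstMatrix) -> str:
    """Neighbor-joining newick over the (clamped) pairwise Fst distances."""
    if len(fst.populations) < 3:
        raise ValueError("cladogram needs at least 3 populations")
    dm = DistanceMatrixT(list(fst.populations), fst.values)
    tree = build_nj_tree(dm)
    return str(tree).strip()
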