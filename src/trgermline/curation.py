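"""False-positive filters: stop codons and operationally indistinguishable genes.

Highly similar V paralogs attract mis-mapped short reads, so a mutation seen
in novel alleles of two such genes at the same (aligned) position is more
plausibly a mapping artifact than two independent germline events.  Genes
that share a neighbor-joining clade with branch lengths at or below a small
threshold (default 0.02) are grouped as *operationally indistinguishable*
(OI); novel alleles carrying a mutation shared across genes of one group are
removed, unless the mutation is also present in a known database allele.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .allele_caller import AlleleCall, diff_sequences
from .locus_model import GeneAnnotation, KnownAlleleDB

log = logging.getLogger(__name__)

OI_BRANCH_THRESHOLD = 0.02


@dataclass
class OIGroup:
    """A maximal set of operationally indistinguishable V genes."""

    locus: str
    member_genes: frozenset[str]
    supporting_branch_lengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValueError("an OI group needs at least two genes")


@dataclass
class DistanceMatrixT:
    """Symmetric non-negative distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.values, ids=self.labels)


@dataclass
class FilterDecision:
    allele_id: str
    gene_name: str
    kept: bool
    filter: str
    reason: str = ""
    evidence: str = ""


def pairwise_gene_distances(sequences: Mapping[str, str]) -> DistanceMatrixT:
    """p-distance (mismatched columns / aligned length) between gene references.

    Equal-length sequences are compared directly; otherwise a unit-cost
    global alignment is used and gap columns count as differences.
    """
    labels = sorted(sequences)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences for a tree-ready matrix")
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sequences[labels[i]], sequences[labels[j]]
        if len(a) == len(b):
            d = sum(x != y for x, y in zip(a, b)) / len(a)
        else:
            muts = diff_sequences(a, b)
            aligned_len = max(len(a), len(b))
            d = sum(max(len(r), len(q), 1) for _, r, q in muts) / aligned_len
        m[i, j] = m[j, i] = d
    return DistanceMatrixT(labels, m)


def build_nj_tree(dm: DistanceMatrixT) -> TreeNode:
    """Neighbor-joining (Saitou–Nei) tree; negative branch lengths clamped to 0."""
    tree = nj(dm.to_skbio(), neg_as_zero=True)
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy, for reporting only."""
    return tree.root_at_midpoint()


def detect_oi_genes(
    tree: TreeNode,
    threshold: float = OI_BRANCH_THRESHOLD,
    *,
    locus: str = "TRA",
    branch_rule: str = "each_branch",
) -> list[OIGroup]:
    """Group genes whose intra-clade path consists only of short branches.

    Two tips are OI-related when, under ``branch_rule='each_branch'``, every
    branch on the unrooted path between them has length ≤ threshold, or,
    under ``'path_sum'``, the total path length is ≤ threshold.  Maximal
    groups are the connected components of this relation.
    """
    if branch_rule not in ("each_branch", "path_sum"):
        raise ValueError("branch_rule must be 'each_branch' or 'path_sum'")
    tips = list(tree.tips())
    names = [t.name for t in tips]
    related: dict[str, set[str]] = {n: set() for n in names}
    pair_branches: dict[frozenset, tuple[float, ...]] = {}
    for a, b in itertools.combinations(tips, 2):
        lengths = _path_branch_lengths(tree, a, b)
        ok = (
            all(l <= threshold for l in lengths)
            if branch_rule == "each_branch"
            else sum(lengths) <= threshold
        )
        if ok:
            related[a.name].add(b.name)
            related[b.name].add(a.name)
            pair_branches[frozenset((a.name, b.name))] = tuple(lengths)
    groups: list[OIGroup] = []
    seen: set[str] = set()
    for name in names:
        if name in seen or not related[name]:
            continue
        comp = {name}
        stack = [name]
        while stack:
            cur = stack.pop()
            for nxt in related[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    stack.append(nxt)
        seen |= comp
        branches = tuple(
            sorted(
                {
                    l
                    for pair, ls in pair_branches.items()
                    if pair <= comp
                    for l in ls
                }
            )
        )
        groups.append(OIGroup(locus=locus, member_genes=frozenset(comp),
                              supporting_branch_lengths=branches))
    return sorted(groups, key=lambda g: sorted(g.member_genes))


def _path_branch_lengths(tree: TreeNode, a: TreeNode, b: TreeNode) -> list[float]:
    """Branch lengths on the unrooted path between two tips."""
    anc_a = [a] + list(a.ancestors())
    anc_b = [b] + list(b.ancestors())
    set_a = set(map(id, anc_a))
    lca = next(n for n in anc_b if id(n) in set_a)
    lengths = []
    for node in anc_a:
        if node is lca:
            break
        lengths.append(node.length or 0.0)
    for node in anc_b:
        if node is lca:
            break
        lengths.append(node.length or 0.0)
    # an unrooted NJ tree is stored with a trifurcating root; the root itself
    # contributes no branch, and lengths of None (root edges) count as 0
    return lengths


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_stop_codons(
    alleles: Sequence[AlleleCall],
    annotations: Mapping[str, GeneAnnotation],
) -> tuple[list[AlleleCall], list[FilterDecision]]:
    """Remove alleles of functional/ORF genes whose translation has an internal stop.

    Pseudogenes are exempt.  Relies on ``has_internal_stop`` computed during
    allele annotation (standard genetic code, annotated frame).
    """
    kept: list[AlleleCall] = []
    removed: list[FilterDecision] = []
    for a in alleles:
        ann = annotations[a.gene_name]
        if ann.functionality != "pseudogene" and a.has_internal_stop:
            a.category = "filtered"
            a.filter_reason = "stop_codon"
            removed.append(
                FilterDecision(a.allele_id, a.gene_name, False, "stop_codon",
                               "internal stop codon in coding translation")
            )
        else:
            kept.append(a)
    return kept, removed


def _aligned_position_map(ref_a: str, ref_b: str) -> dict[int, int]:
    """Map positions of gene A's reference onto gene B's reference frame."""
    if len(ref_a) == len(ref_b):
        return {i: i for i in range(len(ref_a))}
    from .allele_caller import _global_aligner

    aln = _global_aligner().align(ref_b, ref_a)[0]
    mapping: dict[int, int] = {}
    b_coords, a_coords = aln.aligned
    for (bs, be), (as_, ae) in zip(b_coords, a_coords):
        for off in range(be - bs):
            mapping[as_ + off] = bs + off
    return mapping


def filter_oi_shared_mutations(
    alleles: Sequence[AlleleCall],
    oi_groups: Sequence[OIGroup],
    db: KnownAlleleDB,
    reference_seqs: Mapping[str, str],
) -> tuple[list[AlleleCall], list[FilterDecision]]:
    """Remove novel OI-gene alleles whose mutation recurs in a paralog's novel allele.

    Within each OI group, gene-local mutation positions are mapped to a
    common frame (the alphabetically first member gene) by aligning the gene
    references.  A novel allele is removed iff one of its mutations (aligned
    position + alt base) also occurs in a novel allele of *another* group
    member — unless that aligned mutation occurs in at least one known
    database allele of any member gene, which rescues it (a recurrent known
    polymorphism, not a mapping artifact).

    Mutations here are taken against the gene reference sequence (the
    coordinate frame shared by all alleles of a gene).
    """
    kept: list[AlleleCall] = []
    removed: list[FilterDecision] = []
    by_gene: dict[str, list[AlleleCall]] = {}
    for a in alleles:
        by_gene.setdefault(a.gene_name, []).append(a)

    flagged: dict[int, FilterDecision] = {}
    for group in oi_groups:
        members = sorted(group.member_genes)
        anchor = members[0]
        if any(g not in reference_seqs for g in members):
            missing = [g for g in members if g not in reference_seqs]
            raise ValueError(f"OI group {members}: no reference sequence for {missing}")
        maps = {g: _aligned_position_map(reference_seqs[g], reference_seqs[anchor])
                for g in members}

        def aligned_mutations(gene: str, seq: str) -> set[tuple[int, str]]:
            out = set()
            for pos, _ref, alt in diff_sequences(seq, reference_seqs[gene]):
                apos = maps[gene].get(pos)
                if apos is not None and len(alt) == 1:
                    out.add((apos, alt))
            return out

        # rescue set: aligned mutations present in any known allele of any member
        rescue: set[tuple[int, str]] = set()
        for gene in members:
            leader_len = 0
            for rec in db.alleles_for(gene):
                seq = rec.sequence
                ref = reference_seqs[gene]
                if len(seq) != len(ref) and not rec.has_leader:
                    # leaderless record: compare over the reference tail
                    pad = len(ref) - len(seq)
                    if pad > 0:
                        seq = ref[:pad] + seq
                rescue |= aligned_mutations(gene, seq)

        novel_muts: dict[str, dict[tuple[int, str], list[str]]] = {}
        for gene in members:
            for a in by_gene.get(gene, []):
                if a.known_match is not None:
                    continue
                for m in aligned_mutations(gene, a.sequence):
                    novel_muts.setdefault(gene, {}).setdefault(m, []).append(a.allele_id)

        for gene in members:
            for a in by_gene.get(gene, []):
                if a.known_match is not None:
                    continue
                for m in aligned_mutations(gene, a.sequence):
                    if m in rescue:
                        continue
                    partners = [
                        (g, ids)
                        for g, muts in novel_muts.items()
                        if g != gene and m in muts
                        for ids in [muts[m]]
                    ]
                    if partners:
                        flagged[id(a)] = FilterDecision(
                            a.allele_id, gene, False, "oi_shared_mutation",
                            f"mutation pos={m[0]} alt={m[1]} shared with "
                            + ",".join(i for _, ids in partners for i in ids),
                            evidence=";".join(g for g, _ in partners),
                        )
                        break

    for a in alleles:
        dec = flagged.get(id(a))
        if dec is None:
            kept.append(a)
        else:
            a.category = "filtered"
            a.filter_reason = "oi_shared_mutation"
            removed.append(dec)
    return kept, removed


def curate_alleles(
    alleles: Sequence[AlleleCall],
    annotations: Mapping[str, GeneAnnotation],
    db: KnownAlleleDB,
    reference_seqs: Mapping[str, str],
    *,
    oi_threshold: float = OI_BRANCH_THRESHOLD,
    branch_rule: str = "each_branch",
) -> tuple[list[AlleleCall], list[FilterDecision], list[OIGroup]]:
    """Apply both filters; the two commute, stop-codon filter runs first.

    OI groups are detected per locus from NJ trees over V-gene references
    (skipped when a locus has fewer than 3 V genes, in which case raw
    pairwise distances are thresholded directly).
    """
    v_by_locus: dict[str, dict[str, str]] = {}
    for name, ann in annotations.items():
        if ann.segment_type == "V" and name in reference_seqs:
            v_by_locus.setdefault(ann.locus, {})[name] = reference_seqs[name]
    oi_groups: list[OIGroup] = []
    for locus, seqs in sorted(v_by_locus.items()):
        if len(seqs) >= 3:
            dm = pairwise_gene_distances(seqs)
            tree = build_nj_tree(dm)
            oi_groups.extend(
                detect_oi_genes(tree, oi_threshold, locus=locus, branch_rule=branch_rule)
            )
        elif len(seqs) == 2:
            (g1, s1), (g2, s2) = sorted(seqs.items())
            d = sum(x != y for x, y in zip(s1, s2)) / max(len(s1), 1)
            if d / 2 <= oi_threshold:
                oi_groups.append(OIGroup(locus, frozenset((g1, g2)), (d / 2, d / 2)))

    kept, removed_stop = filter_stop_codons(alleles, annotations)
    kept, removed_oi = filter_oi_shared_mutations(kept, oi_groups, db, reference_seqs)
    return kept, removed_stop + removed_oi, oi_groups
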