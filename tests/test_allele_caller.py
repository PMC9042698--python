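import numpy as np
import pytest

from trgermline.allele_caller import (
    AlleleCall,
    classify,
    collapse_haplotypes,
    count_nonsynonymous,
    diff_sequences,
    extract_rss_records,
    match_known,
    mutation_profile,
    sort_and_name,
)
from trgermline.haplotyper import HaplotypeSequence
from trgermline.locus_model import (
    CANONICAL_HEPTAMER,
    KnownAllele,
    KnownAlleleDB,
    extract_gene_reference,
)

from .conftest import make_toy_annotation, random_dna

# independent codon table used as the translation oracle
_CODON = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def hap(seq, sample="s0", phase=0, gene="TOY1", mode="complete"):
    return HaplotypeSequence(sample, phase, gene, mode, seq)


def make_allele(seq, count=10, gene="TOY1", mode="complete"):
    return AlleleCall(
        gene_name=gene,
        sequence=seq,
        haplotype_count=count,
        supporting_haplotypes=[(f"s{i}", i % 2) for i in range(count)],
        region_mode=mode,
    )


class TestCollapse:
    def test_multiset_counts(self):
        seqs = ["AAA"] * 14 + ["CCC"] * 4 + ["GGG"] * 2
        haps = [hap(s, sample=f"s{i}", phase=i % 2) for i, s in enumerate(seqs)]
        calls = collapse_haplotypes(haps)
        assert sorted(c.haplotype_count for c in calls) == [2, 4, 14]
        assert sum(c.haplotype_count for c in calls) == len(haps)

    def test_all_identical_single_allele(self):
        haps = [hap("ACGT", sample=f"s{i}") for i in range(20)]
        calls = collapse_haplotypes(haps)
        assert len(calls) == 1 and calls[0].haplotype_count == 20

    def test_randomized_cohort_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        seqs = [random_dna(6, seed=int(rng.integers(5))) for _ in range(60)]
        haps = [hap(s, sample=f"s{i}") for i, s in enumerate(seqs)]
        calls = collapse_haplotypes(haps)
        # hash-free oracle: count by pairwise string comparison
        oracle = []
        for s in seqs:
            for entry in oracle:
                if entry[0] == s:
                    entry[1] += 1
                    break
            else:
                oracle.append([s, 1])
        assert sorted(c.haplotype_count for c in calls) == sorted(n for _, n in oracle)
        assert {c.sequence for c in calls} == {s for s, _ in oracle}

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError, match="multiple genes"):
            collapse_haplotypes([hap("AAA", gene="G1"), hap("AAA", gene="G2")])


class TestSortAndName:
    def test_descending_ids(self):
        alleles = [make_allele("AAA", 4), make_allele("CCC", 14), make_allele("GGG", 2)]
        named = sort_and_name("TOY1", alleles)
        assert [a.allele_id for a in named] == ["TOY1_01", "TOY1_02", "TOY1_03"]
        assert [a.haplotype_count for a in named] == [14, 4, 2]

    def test_tie_broken_lexicographically(self):
        named = sort_and_name("G", [make_allele("TTT", 5), make_allele("AAA", 5)])
        assert [a.sequence for a in named] == ["AAA", "TTT"]

    def test_three_digit_padding_past_99(self):
        alleles = [make_allele(f"{i:03d}", count=1) for i in range(101)]
        named = sort_and_name("G", alleles)
        assert named[0].allele_id == "G_001" and named[-1].allele_id == "G_101"


class TestClassify:
    @pytest.mark.parametrize(
        "count,known,expected",
        [
            (3, False, "discarded"),
            (3, True, "discarded"),
            (4, False, "AS3"),
            (4, True, "AS1"),
            (18, False, "AS3"),
            (19, False, "AS2"),
            (120, True, "AS1"),
        ],
    )
    def test_boundaries(self, count, known, expected):
        a = make_allele("ACGT", count)
        a.known_match = (
            None if not known else type("KM", (), {"allele_id": "X*01", "match_mode": "complete"})()
        )
        assert classify(a) == expected


class TestMatchKnown:
    @pytest.fixture
    def setting(self, toy_reference, toy_ann):
        ref = extract_gene_reference(toy_reference, toy_ann)
        db = KnownAlleleDB()
        db.add(KnownAllele("TOY1*01", ref))
        db.add(KnownAllele("TOY1*02", ref[9:], has_leader=False,
                           region_covered="v_exon_only"))
        return ref, db, toy_ann

    def test_complete_exact_match(self, setting):
        ref, db, ann = setting
        a = make_allele(ref)
        m = match_known(a, db, ann, "complete")
        assert m.allele_id == "TOY1*01" and m.match_mode == "complete"

    def test_leader_difference_matches_partial_record(self, setting):
        ref, db, ann = setting
        mutated_leader = ("A" if ref[0] != "A" else "C") + ref[1:]
        a = make_allele(mutated_leader)
        m = match_known(a, db, ann, "complete")
        assert m.allele_id == "TOY1*02" and m.match_mode == "overlap_partial"

    def test_v_exon_mismatch_no_match(self, setting):
        ref, db, ann = setting
        pos = 15
        mutated = ref[:pos] + ("A" if ref[pos] != "A" else "C") + ref[pos + 1:]
        assert match_known(make_allele(mutated), db, ann, "complete") is None
        v_allele = make_allele(mutated[9:], mode="v_exon_only")
        assert match_known(v_allele, db, ann, "v_exon_only") is None

    def test_gene_absent_from_db_returns_none(self, setting):
        ref, db, ann = setting
        a = make_allele(ref, gene="GHOST")
        assert match_known(a, db, ann) is None


class TestMutationProfile:
    @pytest.fixture
    def setting(self, toy_reference, toy_ann):
        ref = extract_gene_reference(toy_reference, toy_ann)
        db = KnownAlleleDB()
        db.add(KnownAllele("TOY1*01", ref))
        return ref, db, toy_ann

    def test_identical_zero_mutations(self, setting):
        ref, db, ann = setting
        nearest, muts, counts = mutation_profile(make_allele(ref), db, ann)
        assert nearest == "TOY1*01" and muts == []
        assert counts == {"complete": 0, "v_exon_only": 0}

    def test_leader_substitution_region_arithmetic(self, setting):
        ref, db, ann = setting
        mutated = ("A" if ref[0] != "A" else "C") + ref[1:]
        _, _, counts = mutation_profile(make_allele(mutated), db, ann)
        assert counts == {"complete": 1, "v_exon_only": 0}

    def test_three_edits_match_hamming_oracle(self, setting):
        ref, db, ann = setting
        positions = [2, 11, 25]
        seq = list(ref)
        for p in positions:
            seq[p] = "A" if seq[p] != "A" else "G"
        mutated = "".join(seq)
        _, muts, counts = mutation_profile(make_allele(mutated), db, ann)
        hamming = sum(a != b for a, b in zip(mutated, ref))
        assert counts["complete"] == hamming == 3
        assert [p for p, _, _ in muts] == positions
        assert counts["v_exon_only"] <= counts["complete"]

    def test_nearest_tie_prefers_lowest_number(self, setting):
        ref, db, ann = setting
        variant = ref[:-1] + ("A" if ref[-1] != "A" else "G")
        db.add(KnownAllele("TOY1*02", variant))
        # one mutation from *01 and from *02 differently; equidistant sequence:
        mid = ref[:5] + ("A" if ref[5] != "A" else "G") + ref[6:]
        nearest, _, _ = mutation_profile(make_allele(mid), db, ann)
        assert nearest == "TOY1*01"

    def test_no_known_allele_profiles_vs_reference(self, toy_reference, toy_ann):
        ref = extract_gene_reference(toy_reference, toy_ann)
        a = make_allele(ref, gene="TOY1")
        a.applied_variants = [(3, "A", "C")]
        nearest, muts, _ = mutation_profile(a, KnownAlleleDB(), toy_ann)
        assert nearest is None and muts == [(3, "A", "C")]

    def test_indel_counts_one_mutating_position(self, setting):
        ref, db, ann = setting
        deleted = ref[:12] + ref[14:]
        _, muts, counts = mutation_profile(make_allele(deleted), db, ann)
        assert counts["complete"] == 1
        assert len(muts[0][1]) - len(muts[0][2]) == 2  # one 2-bp deletion event


class TestCountNonsynonymous:
    def oracle(self, a, b):
        syn = nonsyn = 0
        for i in range(0, len(a) - 2, 3):
            ca, cb = a[i:i + 3], b[i:i + 3]
            if ca != cb:
                if _CODON[ca] == _CODON[cb]:
                    syn += 1
                else:
                    nonsyn += 1
        return syn, nonsyn

    def test_synonymous_third_position(self, toy_ann):
        ref = "ATGGATCAT" * 4  # M D H repeated, no stops
        mutated = ref[:5] + "C" + ref[6:]  # GAT -> GAC, still D
        assert count_nonsynonymous(mutated, ref, toy_ann)[:2] == (1, 0)

    def test_nonsynonymous_change(self, toy_ann):
        ref = "ATGGATCAT" * 4
        mutated = ref[:5] + "A" + ref[6:]  # GAT -> GAA (D -> E)
        assert count_nonsynonymous(mutated, ref, toy_ann)[:2] == (0, 1)

    def test_two_edit_matches_translation_oracle(self, toy_ann):
        rng = np.random.default_rng(11)
        codons = [c for c in _CODON if _CODON[c] != "*"]
        ref = "".join(rng.choice(codons, size=12))
        seq = list(ref)
        for p in (4, 20):
            choices = [b for b in "ACGT" if b != seq[p]]
            for b in choices:
                cand = seq.copy()
                cand[p] = b
                if "*" not in [_CODON["".join(cand[i:i+3])] for i in range(0, 36, 3)]:
                    seq[p] = b
                    break
        mutated = "".join(seq)
        n_syn, n_nonsyn, stop = count_nonsynonymous(mutated, ref, toy_ann)
        assert (n_syn, n_nonsyn) == self.oracle(mutated, ref)
        assert not stop

    def test_internal_stop_flagged(self, toy_ann):
        ref = "ATGGATCAT" * 4
        mutated = ref[:3] + "TAA" + ref[6:]
        assert count_nonsynonymous(mutated, ref, toy_ann)[2] is True


class TestRSS:
    def test_reference_rss_extraction_and_conservation(self, toy_ann):
        spacer = random_dna(23, seed=5)
        contig = random_dna(130, seed=6) + CANONICAL_HEPTAMER + spacer + "ACAAAAACC" + random_dna(131, seed=7)
        recs = extract_rss_records({"chrS": contig}, toy_ann, [])
        assert len(recs) == 1
        rec = recs[0]
        assert rec.heptamer == CANONICAL_HEPTAMER and rec.conserved_heptamer
        assert rec.nonamer == "ACAAAAACC" and rec.spacer_length == 23

    def test_heptamer_variant_attached(self, toy_ann):
        contig = random_dna(130, seed=6) + CANONICAL_HEPTAMER + random_dna(23, seed=5) + "ACAAAAACC" + random_dna(131, seed=7)
        a = make_allele("X" * 69, mode="with_rss")
        a.allele_id = "TOY1_02"
        # with_rss transcription coords: exons 0-29, RSS 30-68; heptamer pos 3 -> 33
        a.applied_variants = [(32, "C", "T")]
        recs = extract_rss_records({"chrS": contig}, toy_ann, [a])
        assert recs[0].variants == [("TOY1_02", 2, "C", "T")]

    def test_gene_without_rss_skipped(self, toy_reference, toy_ann):
        toy_ann.rss = []
        assert extract_rss_records(toy_reference, toy_ann, []) == []

    def test_minus_strand_rss_read_strandwise(self, toy_ann_minus):
        from .conftest import oracle_revcomp

        spacer = random_dna(23, seed=5)
        rss_t = CANONICAL_HEPTAMER + spacer + "ACAAAAACC"
        # minus-strand gene: genomic RSS interval [100,139) holds revcomp(rss)
        contig = random_dna(100, seed=8) + oracle_revcomp(rss_t) + random_dna(161, seed=9)
        recs = extract_rss_records({"chrS": contig}, toy_ann_minus, [])
        assert recs[0].heptamer == CANONICAL_HEPTAMER
        assert recs[0].nonamer == "ACAAAAACC"
        assert recs[0].conserved_heptamer


class TestDiffSequences:
    @pytest.mark.parametrize("edit", ["snp", "del", "ins"])
    def test_single_edit_events(self, edit):
        ref = random_dna(40, seed=13)
        if edit == "snp":
            q = ref[:7] + ("A" if ref[7] != "A" else "C") + ref[8:]
        elif edit == "del":
            q = ref[:7] + ref[10:]
        else:
            q = ref[:7] + "CAT" + ref[7:]
        muts = diff_sequences(q, ref)
        assert len(muts) == 1  # one mutating event
        pos, r, a = muts[0]
        if edit == "snp":
            assert (pos, r, a) == (7, ref[7], q[7])
        else:
            assert abs(len(r) - len(a)) == 3
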