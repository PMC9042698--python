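import itertools

import numpy as np
import pytest

from trgermline.allele_caller import AlleleCall
from trgermline.curation import DistanceMatrixT, build_nj_tree
from trgermline.haplotyper import PhasedVariantRecord
from trgermline.locus_model import PopulationPanel
from trgermline.popgen import (
    FstMatrix,
    LocusGenotypeMatrix,
    annotate_population,
    build_genotype_matrix,
    fst_cladogram,
    hudson_fst_components,
    pairwise_fst,
    run_pca,
)


def allele_with_samples(samples, allele_id="G_01"):
    return AlleleCall(
        gene_name="G",
        sequence="ACGT",
        haplotype_count=len(samples),
        supporting_haplotypes=[(s, i % 2) for i, s in enumerate(samples)],
        allele_id=allele_id,
    )


@pytest.fixture
def four_pop_panel():
    entries = {}
    for pop, sup in [("YRI", "AFR"), ("LWK", "AFR"), ("PEL", "AMR"), ("CEU", "EUR")]:
        for i in range(6):
            entries[f"{pop}{i}"] = (pop, sup)
    return PopulationPanel(entries)


class TestAnnotatePopulation:
    def test_african_only(self, four_pop_panel):
        a = allele_with_samples(["YRI0", "YRI1", "LWK0", "LWK1", "YRI2"])
        d = annotate_population(a, four_pop_panel)
        assert d.category == "AFR"
        assert d.counts_by_superpopulation == {"AFR": 5, "AMR": 0, "EUR": 0}
        assert sum(d.counts_by_population.values()) == a.haplotype_count

    def test_afr_shared(self, four_pop_panel):
        a = allele_with_samples(["YRI0", "PEL0"])
        assert annotate_population(a, four_pop_panel).category == "AFR_SHARED"

    def test_all_superpopulations(self, four_pop_panel):
        a = allele_with_samples(["YRI0", "PEL0", "CEU0"])
        assert annotate_population(a, four_pop_panel).category == "ALL"

    def test_non_afr(self, four_pop_panel):
        a = allele_with_samples(["PEL0", "PEL1", "CEU0"])
        assert annotate_population(a, four_pop_panel).category == "NON_AFR"

    def test_presence_threshold_vs_category_presence(self, four_pop_panel):
        a = allele_with_samples(["YRI0", "YRI1", "YRI2", "YRI3", "PEL0"])
        d = annotate_population(a, four_pop_panel, presence_threshold=4)
        assert d.presence_by_population["YRI"] is True
        assert d.presence_by_population["PEL"] is False  # below threshold ...
        assert d.category == "AFR_SHARED"  # ... but still counts for the category

    def test_unknown_sample_strict_vs_lenient(self, four_pop_panel):
        a = allele_with_samples(["YRI0", "ghost"])
        with pytest.raises(KeyError):
            annotate_population(a, four_pop_panel)
        d = annotate_population(a, four_pop_panel, strict=False)
        assert d.total() == 1

    def test_category_partition_exhaustive(self, four_pop_panel):
        for combo_len in range(1, 4):
            for sups in itertools.combinations(["YRI0", "PEL0", "CEU0"], combo_len):
                d = annotate_population(allele_with_samples(list(sups)), four_pop_panel)
                assert d.category in ("ALL", "AFR", "AFR_SHARED", "NON_AFR")


class TestGenotypeMatrix:
    def rec(self, pos, gts, ref="A", alts=("G",)):
        return PhasedVariantRecord("chrS", pos, ref, alts, gts)

    def test_dosage_matches_phased_sum(self, small_panel):
        samples = small_panel.samples
        gts1 = {s: ((0, 1) if i % 2 else (1, 1)) for i, s in enumerate(samples)}
        gts2 = {s: (0, 0) for s in samples}
        gts2[samples[0]] = (0, 1)
        recs = [self.rec(10, gts1), self.rec(20, gts2)]
        m = build_genotype_matrix(recs, "chrS", 0, 100, small_panel)
        assert m.dosages.shape == (10, 2)
        for i, s in enumerate(samples):
            assert m.dosages[i, 0] == sum(gts1[s])
            assert m.dosages[i, 1] == sum(gts2[s])

    def test_monomorphic_and_nonsnp_excluded(self, small_panel):
        samples = small_panel.samples
        mono = {s: (1, 1) for s in samples}
        poly = {s: ((0, 1) if i == 0 else (0, 0)) for i, s in enumerate(samples)}
        recs = [
            self.rec(10, mono),
            self.rec(20, poly),
            self.rec(30, poly, ref="AT", alts=("A",)),  # indel
            self.rec(40, poly, alts=("G", "T")),  # multi-allelic
        ]
        m = build_genotype_matrix(recs, "chrS", 0, 100, small_panel)
        assert [p for p, _, _ in m.sites] == [20]

    def test_empty_site_list_errors(self, small_panel):
        with pytest.raises(ValueError):
            build_genotype_matrix([], "chrS", 0, 100, small_panel)


class TestPCA:
    def cluster_matrix(self):
        # 6 samples, two clusters fixed for disjoint variant sets
        d = np.array(
            [
                [2, 2, 0, 0],
                [2, 2, 0, 0],
                [2, 2, 0, 0],
                [0, 0, 2, 2],
                [0, 0, 2, 2],
                [0, 0, 2, 2],
            ],
            dtype=np.int8,
        )
        sites = [(i + 1, "A", "G") for i in range(4)]
        return LocusGenotypeMatrix([f"s{i}" for i in range(6)], sites, d)

    def test_pc1_separates_clusters(self):
        coords, evr = run_pca(self.cluster_matrix(), n_components=2)
        pc1 = coords[:, 0]
        assert np.all(np.sign(pc1[:3]) == np.sign(pc1[0]))
        assert np.all(np.sign(pc1[3:]) == -np.sign(pc1[0]))
        assert evr[0] == pytest.approx(1.0)

    def test_all_identical_zero_coordinates(self):
        d = np.ones((4, 3), dtype=np.int8)
        m = LocusGenotypeMatrix([f"s{i}" for i in range(4)],
                                [(i + 1, "A", "G") for i in range(3)], d)
        coords, evr = run_pca(m, n_components=1)
        # identical samples: rank 0, components truncated away
        assert coords.shape == (4, 0) and evr.size == 0

    def test_explained_variance_sums_below_one(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        m = LocusGenotypeMatrix([f"s{i}" for i in range(12)],
                                [(i + 1, "A", "G") for i in range(8)], d)
        _, evr = run_pca(m, n_components=3)
        assert 0 < evr.sum() <= 1 + 1e-12

    def test_duplicating_samples_keeps_directions(self):
        m = self.cluster_matrix()
        coords, _ = run_pca(m, n_components=1)
        dup = LocusGenotypeMatrix(m.samples + [s + "b" for s in m.samples], m.sites,
                                  np.vstack([m.dosages, m.dosages]))
        coords2, _ = run_pca(dup, n_components=1)
        # same direction: correlations of PC1 over the repeated block
        c = np.corrcoef(coords[:, 0], coords2[: len(m.samples), 0])[0, 1]
        assert abs(c) == pytest.approx(1.0)


def oracle_hudson(d1, d2):
    """Pure per-site Hudson estimator (ratio of averages), loop form."""
    nums, dens = [], []
    n1, n2 = 2 * d1.shape[0], 2 * d2.shape[0]
    for j in range(d1.shape[1]):
        p1 = d1[:, j].sum() / n1
        p2 = d2[:, j].sum() / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den > 0:
            nums.append(num)
            dens.append(den)
    return sum(nums) / sum(dens)


class TestFst:
    def two_pop_panel(self, n=20):
        entries = {f"p{i}": ("YRI", "AFR") for i in range(n)}
        entries.update({f"q{i}": ("CEU", "EUR") for i in range(n)})
        return PopulationPanel(entries)

    def matrix(self, d, panel):
        return LocusGenotypeMatrix(panel.samples,
                                   [(j + 1, "A", "G") for j in range(d.shape[1])], d)

    def test_identical_frequencies_fst_zero(self):
        panel = self.two_pop_panel(10)
        block = np.tile(np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2]), (3, 1)).T
        d = np.vstack([block, block]).astype(np.int8)
        fst = pairwise_fst(self.matrix(d, panel), panel)
        assert fst.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_fst_one(self):
        panel = self.two_pop_panel(10)
        d = np.vstack([np.zeros((10, 4)), np.full((10, 4), 2)]).astype(np.int8)
        fst = pairwise_fst(self.matrix(d, panel), panel)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_simulated_matches_per_site_oracle(self):
        rng = np.random.default_rng(17)
        panel = self.two_pop_panel(20)
        p_yri = rng.uniform(0.1, 0.9, size=10)
        p_ceu = rng.uniform(0.1, 0.9, size=10)
        d1 = rng.binomial(2, p_yri, size=(20, 10)).astype(np.int8)
        d2 = rng.binomial(2, p_ceu, size=(20, 10)).astype(np.int8)
        d = np.vstack([d1, d2])
        m = self.matrix(d, panel)
        fst = pairwise_fst(m, panel)
        # rows of m.samples: p* first then q* (insertion order)
        assert fst.values[fst.populations.index("YRI"), fst.populations.index("CEU")] == \
            pytest.approx(oracle_hudson(d1, d2), abs=1e-10)

    def test_symmetry_zero_diagonal_and_range(self):
        rng = np.random.default_rng(3)
        panel = self.two_pop_panel(8)
        d = rng.integers(0, 3, size=(16, 6)).astype(np.int8)
        fst = pairwise_fst(self.matrix(d, panel), panel)
        assert np.allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0)
        assert (fst.values >= 0).all() and (fst.values <= 1).all()

    def test_weir_cockerham_close_to_hudson_at_equal_sizes(self):
        rng = np.random.default_rng(9)
        panel = self.two_pop_panel(30)
        d = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        h = pairwise_fst(self.matrix(d, panel), panel, "hudson").values[0, 1]
        w = pairwise_fst(self.matrix(d, panel), panel, "weir_cockerham").values[0, 1]
        assert h == pytest.approx(w, abs=0.05)


class TestFstCladogram:
    def test_distant_population_on_own_branch(self):
        fst = FstMatrix(["A", "B", "C"],
                        np.array([[0, 0.02, 0.5], [0.02, 0, 0.5], [0.5, 0.5, 0]]))
        nwk = fst_cladogram(fst)
        tree = build_nj_tree(DistanceMatrixT(["x"], np.zeros((1, 1)))) if False else None
        import skbio

        t = skbio.TreeNode.read([nwk])
        da_b = t.find("A").distance(t.find("B"))
        da_c = t.find("A").distance(t.find("C"))
        assert da_b < da_c

    def test_label_permutation_invariance(self):
        m = np.array([[0, 0.1, 0.4, 0.45],
                      [0.1, 0, 0.42, 0.47],
                      [0.4, 0.42, 0, 0.12],
                      [0.45, 0.47, 0.12, 0]])
        labels = ["A", "B", "C", "D"]
        nwk1 = fst_cladogram(FstMatrix(labels, m))
        perm = [2, 0, 3, 1]
        m2 = m[np.ix_(perm, perm)]
        nwk2 = fst_cladogram(FstMatrix([labels[i] for i in perm], m2))
        import skbio

        t1 = skbio.TreeNode.read([nwk1])
        t2 = skbio.TreeNode.read([nwk2])
        d1 = {frozenset(p): t1.find(p[0]).distance(t1.find(p[1]))
              for p in itertools.combinations(labels, 2)}
        d2 = {frozenset(p): t2.find(p[0]).distance(t2.find(p[1]))
              for p in itertools.combinations(labels, 2)}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-9)

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            fst_cladogram(FstMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]])))
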