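import numpy as np
import pytest

from trgermline.locus_model import (
    Exon,
    GeneAnnotation,
    PopulationPanel,
    RSSInterval,
)
from trgermline.synthetic_locus import SimulationConfig, generate_fixture

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    """Independent reverse-complement used as the strand oracle in tests."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def make_toy_annotation(strand: str = "+", name: str = "TOY1") -> GeneAnnotation:
    """30-bp gene (9 bp leader + 21 bp V exon) with a 39-bp 3' RSS."""
    if strand == "+":
        exons = [Exon("leader", 100, 109), Exon("v_exon", 109, 130)]
        rss = [RSSInterval(130, 169, "3prime")]
    else:
        rss = [RSSInterval(100, 139, "3prime")]
        exons = [Exon("v_exon", 139, 160), Exon("leader", 160, 169)]
    return GeneAnnotation(name, "TRA", "chrS", strand, "V", "functional", exons, rss, 0)


@pytest.fixture
def toy_reference():
    return {"chrS": random_dna(300, seed=42)}


@pytest.fixture
def toy_ann():
    return make_toy_annotation("+")


@pytest.fixture
def toy_ann_minus():
    return make_toy_annotation("-", name="TOY2")


@pytest.fixture
def small_panel():
    return PopulationPanel(
        {
            **{f"a{i}": ("YRI", "AFR") for i in range(5)},
            **{f"b{i}": ("CEU", "EUR") for i in range(5)},
        }
    )


@pytest.fixture(scope="session")
def fixture_truth(tmp_path_factory):
    """Default synthetic cohort written once per session (seed 7)."""
    outdir = tmp_path_factory.mktemp("fixture")
    truth = generate_fixture(SimulationConfig(rng_seed=7), outdir)
    return truth, outdir
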