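import pytest

from yeastedit import load_registry
from yeastedit.pam_scan import ALL_SYSTEMS, ASCAS12A, SACAS9, SPCAS9
from yeastedit.synth import PlantedSite, SyntheticGenomeSpec, synth_genome


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def systems():
    return {"sp": SPCAS9, "sa": SACAS9, "as12a": ASCAS12A}


# One full-length site per system on each strand, planted in a PAM-free
# (poly-A) background so every scanner hit is a planted one.  Spacers are
# G/C-poor and chosen not to create secondary PAMs for any system on
# either strand (verified by the plant-and-recover tests themselves).
PLANTS = (
    PlantedSite("SpCas9", "ACACTCACACACACACACAC", "AGG", 0, 100, "+"),
    PlantedSite("SpCas9", "ACACTCACACACACACACAC", "AGG", 0, 200, "-"),
    PlantedSite("SaCas9", "ACACTCACACACACACACACA", "ACGAGT", 0, 300, "+"),
    PlantedSite("SaCas9", "ACACTCACACACACACACACA", "ACGAGT", 0, 400, "-"),
    PlantedSite("AsCas12a", "ACACTCACACACACACACACACA", "TTTC", 0, 500, "+"),
    PlantedSite("AsCas12a", "ACACTCACACACACACACACACA", "TTTC", 0, 600, "-"),
)


@pytest.fixture(scope="session")
def planted_genome():
    spec = SyntheticGenomeSpec(
        n_contigs=1,
        contig_len=1000,
        seed=7,
        background="polyA",
        planted_sites=PLANTS,
    )
    return synth_genome(spec)[0], PLANTS


@pytest.fixture(scope="session")
def yeastlike_genome():
    """Random 5-kb contigs at yeast-like GC for statistical checks."""
    spec = SyntheticGenomeSpec(n_contigs=3, contig_len=5000, gc=0.38, seed=11)
    return synth_genome(spec)
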