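import numpy as np
import pytest

from mmescape import synthetic_cohort as sc
from mmescape.genomic_core import BinGrid, GenomicInterval, LocusDef
from mmescape.variant_consequence import bcma_synthetic_cds, bcma_synthetic_domains


@pytest.fixture(scope="session")
def bcma_cds():
    return bcma_synthetic_cds()


@pytest.fixture(scope="session")
def bcma_domains():
    return bcma_synthetic_domains()


@pytest.fixture(scope="session")
def small_grid():
    """10 bins of 100 bp on one chromosome."""
    return BinGrid.uniform({"1": 1000}, 100)


@pytest.fixture(scope="session")
def mm2_truth():
    return sc.build_truth(sc.preset_scenario("MM2-like"))


@pytest.fixture(scope="session")
def mm2_truth_noise_free():
    return sc.build_truth(sc.noise_free(sc.preset_scenario("MM2-like")))


@pytest.fixture(scope="session")
def mm31_truth():
    return sc.build_truth(sc.preset_scenario("MM31-like"))


def two_clone_truth(n_cells=60, noise_free=True, seed=0):
    """A minimal 2-clone cohort: diploid founder + 10-bin deletion subclone."""
    cfg = sc.CohortConfig(
        chrom_lengths={"1": 2_000_000},
        clones=(
            sc.CloneSpec("A", "normal", (), {"t": 0.5}),
            sc.CloneSpec(
                "B", "normal",
                (sc.CNEventSpec(GenomicInterval("1", 200_001, 400_000), delta=-1),),
                {"t": 0.5},
            ),
        ),
        n_cells={"t": n_cells},
        seed=seed,
    )
    return sc.build_truth(sc.noise_free(cfg) if noise_free else cfg)
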