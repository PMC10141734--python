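import pytest

import rearingnet as rn
from rearingnet.records import (EmergenceRecord, FlySpecies, Origin, PlantTaxon,
                                RearingDataset, ResourceType, SampleUnit)

P1, P2 = "2007-2008", "2018-2019"


@pytest.fixture(scope="session")
def paper():
    """The packaged study tables."""
    return rn.load_paper_fixture()


@pytest.fixture(scope="session")
def synthetic():
    """One study-scale synthetic survey with its generative truth."""
    return rn.generate_dataset(rn.SimulationConfig(), 42)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small survey (10 taxa x 5 species) for brute-force comparisons."""
    cfg = rn.SimulationConfig(n_fly_species=5, n_host_taxa=10,
                              samples_per_period=40, density_per_g=5.0)
    return rn.generate_dataset(cfg, 7)


@pytest.fixture()
def tiny_dataset():
    """Hand-built survey: 3 taxa in 3 families, 3 flies, 4 samples.

    Taxon T1 has one productive sample (100 g, 30 flies) and one empty
    sample (50 g), so its empty-mass percentage is 33.33 and its
    density 0.30 flies/g.
    """
    taxa = [
        PlantTaxon("T1", "Ananas comosus", "Bromeliaceae", Origin.NEOTROPICAL,
                   ResourceType.FLESHY_FRUIT),
        PlantTaxon("T2", "Musa x paradisiaca", "Musaceae", Origin.EXOTIC,
                   ResourceType.FLESHY_FRUIT),
        PlantTaxon("T3", "Daucus carota", "Apiaceae", Origin.EXOTIC,
                   ResourceType.ROOT_TUBER),
    ]
    species = [
        FlySpecies("X", "Drosophila simulans", Origin.EXOTIC),
        FlySpecies("Y", "Drosophila cardini", Origin.NEOTROPICAL),
        FlySpecies("Z", "Zaprionus indianus", Origin.EXOTIC),
    ]
    samples = [
        SampleUnit("S1", P1, "T1", 100.0),
        SampleUnit("S2", P1, "T1", 50.0),
        SampleUnit("S3", P1, "T2", 10.0),
        SampleUnit("S4", P2, "T3", 20.0),
    ]
    emergences = [
        EmergenceRecord("S1", "X", 30),
        EmergenceRecord("S3", "X", 2),
        EmergenceRecord("S3", "Y", 1),
        EmergenceRecord("S4", "Y", 5),
    ]
    return RearingDataset(taxa, species, samples, emergences)
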