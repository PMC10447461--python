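import numpy as np
import pytest

import dropmicro as dm


@pytest.fixture(scope="session")
def toy_design() -> dm.BeadPrimerDesign:
    return dm.BeadPrimerDesign.toy(seed=0, cardinalities=(4, 4, 2))


@pytest.fixture(scope="session")
def toy_whitelist(toy_design) -> dm.BarcodeWhitelist:
    return dm.build_whitelist(toy_design)


@pytest.fixture(scope="session")
def two_species_library() -> dm.SimulatedLibrary:
    """A small error-free two-species library reused across tests."""
    profiles = [
        dm.make_species_profile("ecoli", seed=1),
        dm.make_species_profile("bsub", seed=2),
    ]
    config = dm.SimConfig(
        species=profiles,
        cells_per_species=[20, 20],
        umi_per_cell_log_mean=np.log(200.0),
        seed=3,
    )
    return dm.simulate_library(config)


@pytest.fixture(scope="session")
def two_species_demux(two_species_library):
    lib = two_species_library
    return dm.demux_reads(lib.r1, lib.r2, lib.whitelist, lib.design)
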