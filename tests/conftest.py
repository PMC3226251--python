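import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from assaynet import (
    ActivityTable,
    AssayInfo,
    MarkerSets,
    SyntheticConfig,
    build_bipartite,
    gen_markers,
    gen_ppi,
)

PUBLISHED_TOP10_ROWS = [
    ("SULT1E1", 1.4744, 5.1837, 17),
    ("WEE1", 1.3499, 3.1641, 47),
    ("RGS7", 1.3440, 3.0462, 20),
    ("SMN2", 1.6241, 5.8903, 28),
    ("RNGTT", 1.7738, 4.2353, 100),
    ("STK16", 1.6785, 3.9232, 34),
    ("PAK7", 1.7091, 3.8467, 30),
    ("NEK2", 1.7952, 3.5328, 47),
    ("YWHAG", 1.8603, 3.3451, 339),
    ("MAPK10", 1.6685, 3.0371, 27),
]

PUBLISHED_TOP10_ORDER = ["SULT1E1", "WEE1", "RGS7", "SMN2", "RNGTT",
                "STK16", "PAK7", "NEK2", "YWHAG", "MAPK10"]


def small_table() -> ActivityTable:
    pairs = [("A1", "c1"), ("A1", "c2"), ("A1", "c3"),
             ("A2", "c2"), ("A2", "c3"), ("A3", "c4")]
    meta = {"A1": AssayInfo("target_based", "G1"),
            "A2": AssayInfo("cell_based"),
            "A3": AssayInfo("cell_based")}
    return ActivityTable(pairs=pairs, assay_meta=meta)


@pytest.fixture
def activity_table() -> ActivityTable:
    return small_table()


@pytest.fixture(scope="session")
def ppi_small() -> nx.Graph:
    """300-node preferential-attachment interactome, shared read-only."""
    return gen_ppi(300, 2, rng_seed=11)


@pytest.fixture(scope="session")
def ppi_large() -> nx.Graph:
    """2000-node interactome for the statistical-behaviour tests."""
    return gen_ppi(2000, 3, rng_seed=7)


@pytest.fixture(scope="session")
def markers_large(ppi_large) -> MarkerSets:
    cfg = SyntheticConfig(proximity_rho=5.0, rng_seed=7)
    return gen_markers(ppi_large, cfg)
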