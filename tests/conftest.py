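import numpy as np
import pandas as pd
import pytest

from floradisc.catalog import GrowthForm, ProvinceTable, SpeciesRecord
from floradisc.synthetic import SimulationConfig, simulate_catalog


@pytest.fixture(scope="session")
def toy_provinces() -> ProvinceTable:
    """Four provinces on a line: A-B-C-D, with C-D coastal."""
    frame = pd.DataFrame(
        {
            "code": ["A", "B", "C", "D"],
            "area_km2": [100000.0, 150000.0, 80000.0, 60000.0],
            "pop_density": [50.0, 80.0, 200.0, 400.0],
            "coastal": [False, False, True, True],
            "centroid_lat": [30.0, 32.0, 34.0, 36.0],
            "centroid_lon": [100.0, 104.0, 108.0, 112.0],
        }
    ).set_index("code")
    neighbors = {"A": {"B"}, "B": {"C"}, "C": {"D"}}
    return ProvinceTable(frame, neighbors)


@pytest.fixture(scope="session")
def toy_catalog(toy_provinces):
    mk = lambda sid, g, y, f, provs, e=True: SpeciesRecord(
        sid, g, y, GrowthForm(f), frozenset(provs), endemic=e
    )
    return [
        mk("s1", "Abies", 1760, "tree_shrub", {"A"}),
        mk("s2", "Abies", 1800, "tree_shrub", {"A", "B"}, e=False),
        mk("s3", "Carex", 1853, "herb", {"B", "C"}),
        mk("s4", "Carex", 1900, "herb", {"C"}),
        mk("s5", "Carex", 1953, "herb", {"A", "B", "C", "D"}, e=False),
        mk("s6", "Vitis", 1920, "vine_liana", {"D"}),
        mk("s7", "Pteris", 1980, "fern", {"C", "D"}),
        mk("s8", "Pteris", 1995, "fern", {"D"}),
    ]


def small_sim_config(seed: int = 0, n_total: int = 2000, **kw) -> SimulationConfig:
    """Scaled-down study conditions keeping the default form proportions."""
    from floradisc.synthetic import DEFAULT_S_TOT

    total = sum(DEFAULT_S_TOT.values())
    s_tot = {f: max(1, round(v * n_total / total)) for f, v in DEFAULT_S_TOT.items()}
    return SimulationConfig(seed=seed, s_tot=s_tot, **kw)


@pytest.fixture(scope="session")
def sim_small():
    """One medium synthetic catalog shared across read-only tests."""
    cfg = small_sim_config(seed=42, n_total=2500)
    return simulate_catalog(cfg)
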