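import numpy as np
import pandas as pd
import pytest

import rhizotype as rz


@pytest.fixture
def small_config():
    """Tiny single-trait trial config for fast unit tests."""
    return rz.SimulationConfig(
        n_genotypes=8,
        n_blocks=3,
        n_plants_per_plot=4,
        trait_names=["y"],
        trait_means=[10.0],
        sigma2_g=[2.0],
        sigma2_b=[0.5],
        sigma2_e=[1.0],
        seed=42,
    )


@pytest.fixture
def small_trial(small_config):
    return rz.simulate_trial(small_config)


@pytest.fixture
def raw_plant_table():
    """Two genotypes x two blocks x two plants with hand-set raw traits."""
    rows = []
    vals = iter(range(1, 9))
    for g in ("A", "B"):
        for b in ("B1", "B2"):
            for p in (1, 2):
                v = next(vals)
                rows.append(
                    {
                        "genotype": g,
                        "block": b,
                        "plant": p,
                        "culled": False,
                        "total_root_length": 1000.0 * v,
                        "root_length_diam2": 300.0 * v,
                        "root_length_diam3": 200.0 * v,
                        "root_dry_biomass": 0.5 * v,
                        "shoot_dry_biomass": 4.5 * v,
                    }
                )
    return pd.DataFrame(rows)


def quadrant_fixture_matrix() -> pd.DataFrame:
    """Eight genotypes with hand-built median structure over 2 root and
    2 shoot traits.

    Per trait exactly four genotypes sit above and four below the median, so
    the expected assignment is known by construction:
    A, B -> I; C -> II; D, E -> III; F -> IV; G, H -> UNASSIGNED
    (G mixes its root traits, H mixes them the other way).
    """
    # per-trait rank order, rank 8 = largest
    r1 = {"A": 8, "B": 7, "C": 6, "G": 5, "D": 4, "E": 3, "F": 2, "H": 1}
    r2 = {"A": 8, "B": 7, "C": 6, "H": 5, "D": 4, "E": 3, "F": 2, "G": 1}
    s1 = {"A": 8, "B": 7, "F": 6, "G": 5, "C": 4, "D": 3, "E": 2, "H": 1}
    s2 = {"A": 7, "B": 8, "F": 5, "G": 6, "C": 3, "D": 4, "E": 1, "H": 2}
    gids = list("ABCDEFGH")
    return pd.DataFrame(
        {
            "root_t1": [float(r1[g]) for g in gids],
            "root_t2": [float(r2[g]) for g in gids],
            "shoot_t1": [float(s1[g]) for g in gids],
            "shoot_t2": [float(s2[g]) for g in gids],
        },
        index=pd.Index(gids, name="genotype"),
    )


EXPECTED_QUADRANTS = {
    "A": "I",
    "B": "I",
    "C": "II",
    "D": "III",
    "E": "III",
    "F": "IV",
    "G": "UNASSIGNED",
    "H": "UNASSIGNED",
}


@pytest.fixture
def quadrant_matrix():
    return quadrant_fixture_matrix()
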