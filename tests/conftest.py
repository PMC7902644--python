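import numpy as np
import pandas as pd
import pytest

from fmtengraft.gene_profiles import GeneCountTable
from fmtengraft.synthetic import (
    GeneratorParams,
    Scenario,
    StudyDesign,
    default_scenarios,
    generate_catalogue,
    generate_inoculum,
    simulate_study,
)

SMALL_FAMILIES = (
    ("Lachnospiraceae", "Firmicutes", 8),
    ("Ruminococcaceae", "Firmicutes", 6),
    ("Bacteroidaceae", "Bacteroidetes", 6),
    ("Enterobacteriaceae", "Proteobacteria", 5),
)


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(
        n_msp=25,
        family_table=SMALL_FAMILIES,
        genes_per_msp=(20, 40),
        read_depth=30_000,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_catalogue(small_params):
    return generate_catalogue(small_params)


@pytest.fixture(scope="session")
def small_inoculum(small_params, small_catalogue):
    return generate_inoculum(small_catalogue, small_params)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(mice_per_group=4, days=("D2", "D4", "D15"))


@pytest.fixture(scope="session")
def small_study(small_design, small_params, small_catalogue, small_inoculum):
    """Full 7-group study at reduced scale: 84 samples, known truth."""
    return simulate_study(
        small_design,
        small_params,
        default_scenarios(),
        catalogue=small_catalogue,
        inoculum=small_inoculum,
    )


@pytest.fixture
def toy_counts():
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 0],
            "s2": [6000, 4000, 0],
        },
        index=["g1", "g2", "g3"],
    )
    lengths = pd.Series([100, 400, 250], index=["g1", "g2", "g3"])
    return GeneCountTable(counts=counts, lengths=lengths)


@pytest.fixture(scope="session")
def balanced_response():
    """Balanced 3x2x3 response table with subject effects, fixed seed."""
    rng = np.random.default_rng(42)
    rows = []
    for a in ("MD", "TR", "NaCl"):
        for b in ("W1", "W7"):
            for i in range(4):
                subj = f"{a}-{b}-m{i}"
                base = rng.normal()
                for c in ("D2", "D4", "D15"):
                    rows.append(
                        {
                            "mouse_id": subj,
                            "diluent": a,
                            "week": b,
                            "day": c,
                            "engraftment": 0.5 * base + rng.normal(),
                        }
                    )
    return pd.DataFrame(rows)
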