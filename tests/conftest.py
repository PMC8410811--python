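import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_counts():
    """Small community: 6 OTUs, singletons and doubletons present."""
    return np.array([5, 3, 2, 2, 1, 1])


@pytest.fixture
def toy_newick(tmp_path):
    """Five-tip tree with known branch lengths (total length 13.5)."""
    path = tmp_path / "toy.nwk"
    path.write_text("((A:1,B:2):0.5,(C:3,D:1):2,E:4);\n")
    return path


@pytest.fixture
def triplicate_table():
    """Three identical replicates of a two-analyte sample."""
    rows = []
    for rep in ("R1", "R2", "R3"):
        rows.append({"sample_id": "S", "replicate_id": rep, "analyte": "Cd",
                     "concentration_mg_per_L": 95.0})
        rows.append({"sample_id": "S", "replicate_id": rep, "analyte": "Fe",
                     "concentration_mg_per_L": 39.7})
    return pd.DataFrame(rows)
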