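import numpy as np
import pandas as pd
import pytest

from morphoscreen.design import build_design
from morphoscreen.simulate import SimulationParams, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A desk-scale screen: 3 sub-clones x 1 concentration, 25 compounds,
    120 correlated features, 10 planted reverters."""
    design = build_design(
        n_subclones=3,
        concentrations=(1000.0,),
        n_compounds=25,
        wt_vehicle_wells_per_plate=10,
        ko_vehicle_wells_per_plate=8,
        ko_untreated_wells_per_plate=2,
    )
    params = SimulationParams(n_features=120, n_latent=6, seed=7)
    table, truth = simulate_screen(design, params)
    return design, params, table, truth


@pytest.fixture()
def toy_well_table():
    """Deterministic well-level table with 40 wells and 30 features."""
    rng = np.random.default_rng(11)
    n, p = 40, 30
    meta = pd.DataFrame(
        {
            "plate_id": ["P01"] * (n // 2) + ["P02"] * (n // 2),
            "well": [f"A{i + 1:02d}" for i in range(n // 2)] * 2,
            "subclone_id": ["SC1"] * n,
            "genotype": (["WT"] * 10 + ["KO"] * 10) * 2,
            "treatment": ["VEHICLE"] * n,
            "concentration_nM": [0.0] * n,
        }
    )
    X = rng.standard_normal((n, p))
    feats = pd.DataFrame(X, columns=[f"F{j:03d}" for j in range(p)])
    return pd.concat([meta, feats], axis=1)
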