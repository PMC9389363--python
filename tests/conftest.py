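import numpy as np
import pandas as pd
import pytest

from inflamnet import simulate as sim


@pytest.fixture(scope="session")
def design():
    return sim.generate_study_design()


@pytest.fixture(scope="session")
def planted_modules():
    return [
        sim.PlantedModuleSpec(
            "IBT_HER2_TNBC", 30, {"IBT", "Her2", "TNBC"}, log2_effect=2.0
        ),
        sim.PlantedModuleSpec("HER2_TNBC", 30, {"Her2", "TNBC"}, log2_effect=2.0),
    ]


@pytest.fixture(scope="session")
def study(design, planted_modules):
    """Simulated counts with two planted disease modules + ground truth."""
    counts, truth = sim.generate_expression(
        design,
        planted_modules,
        background_genes=500,
        dispersion=0.05,
        seed=7,
        base_mean_log_sd=0.5,  # keep genes well above the detection floor
    )
    return design, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_expr():
    """4 genes x 4 samples with exact, hand-checkable values."""
    return pd.DataFrame(
        {
            "S1": [10.0, 90.0, 0.0, 4.0],
            "S2": [20.0, 60.0, 10.0, 10.0],
            "S3": [5.0, 80.0, 10.0, 5.0],
            "S4": [1.0, 50.0, 40.0, 9.0],
        },
        index=["G1", "G2", "G3", "G4"],
    )
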