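import numpy as np
import pandas as pd
import pytest

from shmoo.ensemble import EnsembleSummary
from shmoo.fitting import DoseResponseDataset
from shmoo.mesh import build_mesh
from shmoo.params import ModelParams


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def mesh24(params):
    return build_mesh(params.R, params.R_n, 24, 60)


@pytest.fixture(scope="session")
def tiny_mesh(params):
    """Coarse mesh for ensemble-heavy tests (8 radial x 20 angular cells)."""
    return build_mesh(params.R, params.R_n, 8, 20)


def summary_to_dataset(summary: EnsembleSummary) -> DoseResponseDataset:
    """Recast an ensemble summary as a dose-response dataset (simulated
    cells standing in for observed ones)."""
    t = summary.table
    return DoseResponseDataset(
        pd.DataFrame(
            {
                "S_nM": t["S_mean_nM"],
                "n_cells": t["n_reps"],
                "n_shmoo": (t["frac_polarized"] * t["n_reps"]).round(),
                "mean_delay_h": t["mean_delay_h"],
                "sd_delay_h": t["sd_delay_h"],
            }
        ),
        provenance="synthetic",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
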