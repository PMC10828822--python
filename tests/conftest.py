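import numpy as np
import pytest

from tmtd.layout import two_proteome_layout
from tmtd.pipeline import (
    add_eil,
    assign_peptide_classes,
    compute_noise_estimates,
    compute_purity_metrics,
    fit_models,
    records_to_frame,
)
from tmtd.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def layout():
    return two_proteome_layout()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=42, psms_per_run=800))


def run_full_pipeline(sim, min_leaf=100):
    """metrics -> density -> classes -> fit -> EIL on a SimResult, in memory."""
    cfg = sim.config
    _, extracts = compute_purity_metrics(sim.psms, sim.snapshots)
    compute_noise_estimates(sim.psms, sim.snapshots, extracts)
    assign_peptide_classes(sim.psms, min_leaf=min_leaf)
    fits = fit_models(sim.psms, cfg.layout)
    add_eil(sim.psms, fits, cfg.layout)
    frame = records_to_frame(sim.psms, cfg.layout)
    return frame, fits


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
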