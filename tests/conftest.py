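import numpy as np
import pytest

from allneo.peptides import ProteinRecord
from allneo.simulate import SimulationConfig, generate_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """20 random proteins (lengths 30–80), MMR genes on the first four."""
    rng = np.random.default_rng(1234)
    return generate_proteome(20, (30, 80), rng)


@pytest.fixture()
def protein100():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
    return ProteinRecord(protein_id="P1", gene="G1", sequence=seq)


@pytest.fixture()
def small_config(tmp_path):
    """Desk-scale simulation config for fast end-to-end runs."""
    return SimulationConfig(
        n_patients=8,
        mu_wt=20.0,
        n_proteins=30,
        protein_length_range=(50, 100),
        master_seed=42,
    )
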