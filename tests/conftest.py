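import numpy as np
import pytest

from dnabind.datasets import PALBOCICLIB_CTDNA_KB
from dnabind.simulate import SimulationSpec, simulate_titration


@pytest.fixture
def published_kb_series():
    """Published palbociclib/CT-DNA binding constants at four temperatures."""
    return PALBOCICLIB_CTDNA_KB


@pytest.fixture
def clean_titration():
    """Noise-free excess-ligand titration with Kb = 5000, BH intercept 2."""
    spec = SimulationSpec(kb=5000.0, noise_sd=0.0)
    titration, truth = simulate_titration(spec)
    return titration, truth


@pytest.fixture
def titration_csv_text():
    """A 9-row titration table: zero-ligand reference plus 8 fit points."""
    concs = np.linspace(0.0, 2.5e-5, 9)
    rows = ["ligand_conc_M,absorbance"]
    rows += [f"{c:.10g},{0.545 + 3.0e3 * c:.10g}" for c in concs]
    return "\n".join(rows) + "\n"
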