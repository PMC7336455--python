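import numpy as np
import pytest

from pdxgem.dataio import DrugActivityTable, ExpressionMatrix
from pdxgem.simulate import SimConfig, simulate_study


@pytest.fixture
def toy_expr():
    """4 features x 6 samples, deterministic."""
    rng = np.random.default_rng(11)
    values = rng.normal(size=(4, 6))
    return ExpressionMatrix(values, [f"g{i}" for i in range(1, 5)],
                            [f"s{j}" for j in range(1, 7)])


@pytest.fixture
def toy_activity():
    return DrugActivityTable([f"s{j}" for j in range(1, 7)],
                             [-35.0, -12.5, -0.5, 0.0, 18.0, 64.0])


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-signal study used by the slower integration tests."""
    cfg = SimConfig(n_features=300, n_sensitivity=25, n_concordant=25,
                    n_pdx=16, n_patients_ref=120, n_patients_val=80,
                    shared_factor_weight=0.5, block_correlation=0.8, seed=7)
    return simulate_study(cfg)
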