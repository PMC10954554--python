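import warnings

import numpy as np
import pytest

from odontolife.kinship import LifeTable, solve_baseline_fecundity

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def toy_table() -> LifeTable:
    """Three-age toy life table: survival 1 -> 0.5 -> 0.25, reproduction at
    ages 1 and 2, maturity 1. Euler-Lotka gives f = 4/3."""
    t = LifeTable(survival=np.array([0.5, 0.5]), phi=np.array([0.0, 1.0, 1.0]), maturity=1)
    solve_baseline_fecundity(t)
    return t
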