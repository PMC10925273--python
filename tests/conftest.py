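import numpy as np
import pytest

import fepcycle as fc
from fepcycle.constants import KB_KCAL_MOL_K

# Temperature chosen so kB*T = 0.596 kcal/mol, a convenient round thermal
# energy close to room temperature (299.9 K).
KBT = 0.596
T_KBT = KBT / KB_KCAL_MOL_K


@pytest.fixture(scope="session")
def harmonic_system():
    """Spring-constant quadrupling, exact dG = kBT/2 * ln 4 = 0.41312."""
    return fc.ToyAlchemicalSystem("harmonic", k0=1.0, k1=4.0, T=T_KBT)


@pytest.fixture(scope="session")
def harmonic_runs(harmonic_system):
    """Paired forward/backward 20-window runs, 5000 samples per window."""
    fwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(20, "forward"),
                        5000, seed=11)
    bwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(20, "backward"),
                        5000, seed=12)
    return fwd, bwd


@pytest.fixture(scope="session")
def gaussian_system():
    """Per-window Gaussian work model: dG/window = mu - sigma2/(2 kBT)."""
    return fc.ToyAlchemicalSystem("shifted_gaussian_work", mu=1.0, sigma2=0.5,
                                  T=T_KBT)


@pytest.fixture(scope="session")
def gaussian_window_pair(gaussian_system):
    """One-window forward/backward sample pair at n = 1e5."""
    fwd = fc.sample_run(gaussian_system, fc.make_lambda_schedule(1, "forward"),
                        100_000, seed=21)
    bwd = fc.sample_run(gaussian_system, fc.make_lambda_schedule(1, "backward"),
                        100_000, seed=22)
    return fwd.windows[0].samples_dU, bwd.windows[0].samples_dU
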