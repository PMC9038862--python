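import logging

import numpy as np
import pytest

from fracperf.phantom_sim import PerfusionDomain, generate_tree, make_experiment

logging.getLogger("fracperf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def disc_domain() -> PerfusionDomain:
    return PerfusionDomain("disc", (0.0, 0.0), 30.0)


@pytest.fixture(scope="session")
def small_tree(disc_domain):
    """A modest CCO tree reused by read-only tests."""
    return generate_tree(disc_domain, 50, "volume", disc_domain.boundary_point(np.pi),
                         60.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom_set():
    """Reduced-size phantom set (2 per stage) with intermediates kept.

    Smaller trees than the study defaults keep the suite fast; structural
    invariants do not depend on tree size.
    """
    return make_experiment(2, seed=5, keep_intermediates=True,
                           host_n_terminals=120, tumor_n_terminals=50)
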