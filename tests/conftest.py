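import numpy as np
import pytest

from oligofish.panel_assembly import load_probe_table
from oligofish.synthetic_data import FamilySpec, simulate_family


@pytest.fixture(scope="session")
def probe_records():
    """The packaged 26-probe table."""
    return load_probe_table()


@pytest.fixture(scope="session")
def family():
    """Default synthetic homolog family (seed 42, planted conserved window)."""
    spec = FamilySpec()
    ancestor, homologs, truth = simulate_family(spec)
    return spec, ancestor, homologs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_fixed(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
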