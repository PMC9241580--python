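import numpy as np
import pytest

from mrkit.harmonize import HarmonizedInstrument
from mrkit.simulate import make_reference_fixture


@pytest.fixture(scope="session")
def bundle():
    """The deterministic 21-candidate selection fixture."""
    return make_reference_fixture()


def make_instruments(g, G, sG, sg=None, ids=None):
    """Build harmonized instruments directly from effect arrays."""
    g = np.asarray(g, dtype=float)
    G = np.asarray(G, dtype=float)
    sG = np.asarray(sG, dtype=float)
    sg = np.full_like(g, 0.01) if sg is None else np.asarray(sg, dtype=float)
    ids = ids or [f"rs{j}" for j in range(len(g))]
    return [
        HarmonizedInstrument(
            variant_id=ids[j],
            used_id=ids[j],
            beta_exp=float(g[j]),
            se_exp=float(sg[j]),
            beta_out=float(G[j]),
            se_out=float(sG[j]),
        )
        for j in range(len(g))
    ]


@pytest.fixture
def instrument_factory():
    return make_instruments
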