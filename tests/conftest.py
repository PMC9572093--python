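import numpy as np
import pytest

from oxiqspr import parse_structures


@pytest.fixture(scope="session")
def mols():
    """Small panel of parsed molecules used across descriptor tests."""
    source = "\n".join(
        [
            "C methane",
            "CCCC butane",
            "c1ccccc1 benzene",
            "C1CCCCC1 cyclohexane",
            "CCO ethanol",
            "CC1CCc2ccccc2O1 chroman",
        ]
    )
    graphs = parse_structures(source, format="smiles")
    return {g.id: g for g in graphs}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20191)
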