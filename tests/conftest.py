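import pytest

from ssipsolv import DEFAULT_CONSTANTS, DEFAULT_REGISTRY


@pytest.fixture(scope="session")
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


#: the hand-enumerated fixture set: SMILES -> (n_alpha, n_beta)
FIXTURE_COUNTS = {
    "C": (4, 4),  # methane
    "c1ccccc1": (6, 14),  # benzene
    "Cc1ccccc1": (8, 17),  # toluene
    "O": (2, 2),  # water
    "CCO": (6, 7),  # ethanol
    "CCOCC": (10, 12),  # diethyl ether
    "CC(C)=O": (6, 10),  # acetone
    "CC#N": (3, 8),  # acetonitrile
    "CC(C)(C)Cl": (11, 12),  # t-butyl chloride
    "ClCCl": (6, 8),  # dichloromethane
    "ClC(Cl)Cl": (7, 10),  # chloroform
    "ClC(Cl)(Cl)Cl": (8, 12),  # carbon tetrachloride
}
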