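import pytest

from gcpep import MembraneSpec, PEPTIDE_PRESETS, SolutionConditions


@pytest.fixture(scope="session")
def membrane():
    """7POPC:3POPG membrane: XA=0.3, AL=70 A^2, KNa=0.6 /M."""
    return MembraneSpec()


@pytest.fixture(scope="session")
def solution_55():
    return SolutionConditions(pH_bulk=5.5)


@pytest.fixture(scope="session")
def solution_74():
    return SolutionConditions(pH_bulk=7.4)


@pytest.fixture(scope="session")
def mp1():
    return PEPTIDE_PRESETS["MP1"]


@pytest.fixture(scope="session")
def hmp1():
    return PEPTIDE_PRESETS["H-MP1"]
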