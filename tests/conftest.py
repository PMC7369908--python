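import numpy as np
import pytest

from tyrlie.synthetic import reference_table, table4_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    """Packaged study fixture: (deltas by ligand, ligand records by id)."""
    return table4_fixture()


@pytest.fixture(scope="session")
def printed_reference():
    """The published per-ligand reference table as a DataFrame."""
    return reference_table()


@pytest.fixture(scope="session")
def printed_exps(printed_reference):
    """Published experimental binding free energies (kcal/mol) by ligand."""
    sub = printed_reference.dropna(subset=["dG_exp"])
    return dict(zip(sub["ligand_id"], sub["dG_exp"].astype(float)))


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
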