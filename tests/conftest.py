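import numpy as np
import pytest

from hexbind.synthetic import (
    FixtureSpec,
    make_hexamer_fixture,
    make_insser_t3r3_spec,
)


@pytest.fixture(scope="session")
def insser_hexamer():
    """The serotonin-loaded T3R3 hexamer with two tetrahedral Zn sites."""
    return make_hexamer_fixture(make_insser_t3r3_spec(seed=1))


@pytest.fixture(scope="session")
def bare_hexamers():
    """The four canonical hexamer fixtures (no ligands, no zinc)."""
    recipes = {
        "T6": ("T",) * 6,
        "R6": ("R",) * 6,
        "T3Rf3": ("T", "T", "T", "Rf", "Rf", "Rf"),
        "T3R3": ("T", "T", "T", "R", "R", "R"),
    }
    return {
        label: make_hexamer_fixture(FixtureSpec(monomer_states=states, seed=0))
        for label, states in recipes.items()
    }


@pytest.fixture(scope="session")
def zinc_hexamers():
    """Ligand-free hexamers carrying ideal Zn coordination shells."""
    tet = make_hexamer_fixture(
        FixtureSpec(zinc=[("tetrahedral", "CL")], seed=0)
    )
    octa = make_hexamer_fixture(
        FixtureSpec(zinc=[("octahedral", None)], seed=0)
    )
    return {"tetrahedral": tet, "octahedral": octa}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
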