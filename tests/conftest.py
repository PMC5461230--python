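import pytest

from molkit.fixtures import FixtureSpec, generate_fixtures


@pytest.fixture(scope="session")
def fixture_molecules():
    """A deterministic mixed corpus: acyclic, cyclic, aromatic, charged
    and stereo-bearing molecules."""
    return generate_fixtures(FixtureSpec(seed=1, n_molecules=100))


@pytest.fixture(scope="session")
def small_fixture_molecules():
    """Small molecules (<= 10 atoms) for brute-force oracle comparisons."""
    return generate_fixtures(
        FixtureSpec(seed=7, n_molecules=60, min_atoms=3, max_atoms=10)
    )


AROMATIC_CORPUS = [
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1cc[nH]c1",        # pyrrole
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
    "c1cnc[nH]1",        # imidazole
    "c1cncnc1",          # pyrimidine
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncccc2c1",    # quinoline
    "c1ccc2cccc2cc1",    # azulene
    "Cn1cccc1",          # N-methylpyrrole
    "c1cc[nH+]cc1",      # pyridinium
    "c1ccc(cc1)c1ccccc1",  # biphenyl
]
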