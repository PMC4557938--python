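import pytest

from nichecast import synthetic


@pytest.fixture(scope="session")
def study_bundle():
    """The reference study conditions: n=60 genomes, planted transporter signal."""
    return synthetic.generate(synthetic.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def toy():
    """The hand-sized membrane/metabolism worked example."""
    return synthetic.generate_worked_example()


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort for pipeline plumbing tests."""
    return synthetic.SyntheticSpec(
        n_genomes=18, n_enzyme_functions=40, n_transporters=20,
        n_metabolites=30, n_ligands=12, seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return synthetic.generate(small_spec)
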