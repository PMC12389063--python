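"""Shared fixtures: one seeded reference build and cohort per session."""

import pytest

from morus_nrdna import simulate as sim


@pytest.fixture(scope="session")
def build():
    return sim.build_reference(seed=1)


@pytest.fixture(scope="session")
def cohort(build):
    return sim.simulate_cohort(build)


@pytest.fixture(scope="session")
def templates(build):
    return sim.build_its_templates(build)


@pytest.fixture(scope="session")
def species_profiles():
    return sim.default_species_profiles()
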