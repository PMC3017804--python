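import numpy as np
import pytest

from genefam import domain_census, phylo
from genefam.synthetic_data import ForgeConfig, forge_all, forge_genome


@pytest.fixture(scope="session")
def forge():
    """Default forged genome, seed 1 (shared; treat as read-only)."""
    return forge_genome(ForgeConfig(seed=1))


@pytest.fixture(scope="session")
def full_forge():
    """Genome + ESTs + expression for seed 1."""
    return forge_all(ForgeConfig(seed=1))


@pytest.fixture(scope="session")
def profile():
    return domain_census.load_packaged_profile()


@pytest.fixture(scope="session")
def census_hits(forge, profile):
    return domain_census.scan_proteins(forge.proteins, profile,
                                       n_shuffles=300, seed=0)


@pytest.fixture(scope="session")
def family_records(forge):
    members = set(forge.truth.family_members)
    return [r for r in forge.proteins if r.id in members]


@pytest.fixture(scope="session")
def family_tree(family_records):
    msa = phylo.build_msa(family_records)
    return phylo.bootstrap_support(msa, reps=100, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=length))
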