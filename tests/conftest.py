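import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glucotriage import datasets
from glucotriage.synthetic_data import Contact, SimSpec, gen_toy_complex


@pytest.fixture(scope="session")
def reference_descriptors():
    """Descriptor sets for the six reference compounds (structure-derived
    MW/TPSA/HBD/logP joined with supplied logD/pKa)."""
    return datasets.reference_descriptors()


@pytest.fixture(scope="session")
def gtt_means():
    return datasets.gtt_group_means()


@pytest.fixture(scope="session")
def toy_complex():
    """A minimal receptor-ligand complex with one planted contact of
    each kind at known distances."""
    spec = SimSpec(seed=42)
    return gen_toy_complex(spec, contacts=[
        Contact("hydrophobic", "PHE", 3.6),
        Contact("hbond", "ASP", 2.73),
        Contact("pi_cation", "TRP", 4.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(2129)
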