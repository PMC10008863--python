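import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from intronmatch.align import bfe_scheme, sw_scheme
from intronmatch.pipeline import align_models
from intronmatch.simulate import SimSpec, simulate_transcript_models


@pytest.fixture(scope="session")
def bfe():
    return bfe_scheme()


@pytest.fixture(scope="session")
def sw():
    return sw_scheme()


@pytest.fixture(scope="session")
def small_dataset():
    """30-gene synthetic dataset with 25 bp perfect plants in the 3'UTR."""
    spec = SimSpec(n_genes=30, plant_rate=0.8, plant_region="3UTR", seed=3)
    models, truth = simulate_transcript_models(spec)
    return spec, models, truth


@pytest.fixture(scope="session")
def small_oms(small_dataset):
    _, models, _ = small_dataset
    return align_models(models, "BFE")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
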