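import numpy as np
import pytest

from catd.pipeline import PipelineConfig, run_pipeline
from catd.simulator import SimConfig, simulate_cohort, simulate_reference_and_library

RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(RC)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def default_design():
    """Library + reference designed at paper composition (36 probes)."""
    return simulate_reference_and_library(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Default cohort plan at reduced depth with default noise."""
    return simulate_cohort(SimConfig(seed=5, depth=20_000))


CLEAN_CFG = SimConfig(
    seed=13, depth=20_000, error_rate=0.0, junk_fraction=0.0, catd_background=0.0
)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-error, zero-junk, zero-background cohort (oracle round trips)."""
    return simulate_cohort(CLEAN_CFG)


@pytest.fixture(scope="session")
def small_pipeline_result():
    return run_pipeline(PipelineConfig(sim=SimConfig(seed=5, depth=20_000)))
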