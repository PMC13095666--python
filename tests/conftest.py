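import numpy as np
import pandas as pd
import pytest

from mitoscreen import HaplotypePanel, VariantSite, generate_cohort


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """Three-site panel: two cis (one focal) and one trans."""
    return HaplotypePanel(
        (
            VariantSite(100, "C", "T", "cis"),
            VariantSite(500, "A", "G", "cis"),
            VariantSite(900, "G", "T", "trans"),
        ),
        focal_position=100,
        genome_length=16_299,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """500-cell synthetic cohort with the default depletion map."""
    return generate_cohort(500, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
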