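import numpy as np
import pytest

from mirfam.pipeline import run_discovery
from mirfam.simulate import (
    REFERENCE_MATURES,
    default_config,
    default_queries,
    generate_toy_genome,
)

STUDY_SEED = 42


@pytest.fixture(scope="session")
def toy_study():
    """The default synthetic study: genome, annotation, blocks and truth."""
    genome, features, blocks, manifest = generate_toy_genome(default_config(STUDY_SEED))
    return {"genome": genome, "features": features, "blocks": blocks,
            "manifest": manifest}


@pytest.fixture(scope="session")
def discovery(toy_study):
    """Discovery screen run once on the toy study."""
    return run_discovery(
        toy_study["genome"],
        default_queries(),
        REFERENCE_MATURES,
        toy_study["features"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
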