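import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lipotrace import SimConfig, pipeline, reference_subject

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    return SimConfig(seed=0)


@pytest.fixture
def small_counts():
    """Reduced per-well cell counts for fast image-based unit tests."""
    return {"monocyte": 60, "lymphocyte": 180}


@pytest.fixture(scope="session")
def quantified_wells():
    """Two CM and two LP wells at full study-scale cell counts, rendered
    and re-quantified through the image pipeline.  Shared by the
    recovery tests; pooled per treatment."""
    config = SimConfig(seed=7)
    subject = reference_subject()
    seeds = np.random.SeedSequence(7).spawn(4)
    pooled = {}
    for treatment, sub_seeds in (("CM", seeds[:2]), ("LP", seeds[2:])):
        tables = []
        for s in sub_seeds:
            rng = np.random.default_rng(s)
            measured, _, _ = pipeline.simulate_and_quantify_well(
                subject, treatment, config, rng
            )
            tables.append(measured)
        pooled[treatment] = pd.concat(tables, ignore_index=True)
    return pooled
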