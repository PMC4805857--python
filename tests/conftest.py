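import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mrpipe import HarmonisedInstrument, SimulationTruth, generate


@pytest.fixture
def three_snp_instrument():
    """The hand-computed fixture: weights 10000/2500/1111.1, IVW 0.21667."""
    return HarmonisedInstrument(
        ["rs1", "rs2", "rs3"],
        bx=[0.1, 0.2, 0.3],
        se_x=[0.01, 0.01, 0.01],
        by=[0.02, 0.05, 0.06],
        se_y=[0.01, 0.02, 0.03],
    )


@pytest.fixture
def random_instrument_factory():
    """Small random instruments with positive SEs for oracle comparisons."""

    def make(seed, j=None, m=0):
        rng = np.random.default_rng(seed)
        j = j if j is not None else int(rng.integers(3, 13))
        labels = [f"C{i}" for i in range(m)]
        return HarmonisedInstrument(
            [f"rs{i}" for i in range(j)],
            bx=rng.normal(0, 0.05, j),
            se_x=rng.uniform(0.002, 0.01, j),
            by=rng.normal(0, 0.02, j),
            se_y=rng.uniform(0.005, 0.02, j),
            covariate_labels=labels,
            bc=rng.normal(0, 0.02, (j, m)) if m else None,
            se_c=rng.uniform(0.002, 0.01, (j, m)) if m else None,
        )

    return make


@pytest.fixture
def labelled_31snp():
    return generate(SimulationTruth(theta=0.17, seed=11))
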