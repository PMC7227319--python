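import numpy as np
import pandas as pd
import pytest

from pretimeth import MethylationMatrix, SimulationSpec, generate_fixture


@pytest.fixture(scope="session")
def planted_fixture():
    """Small planted study shared by read-only tests: 20 model loci, 40
    feature loci, 100 samples, noise tiers cycling through the four
    accuracy levels, no missingness."""
    spec = SimulationSpec(seed=11)
    return generate_fixture(spec)


@pytest.fixture()
def tiny_matrix():
    data = pd.DataFrame(
        [[0.1, 0.9], [np.nan, 0.5]],
        index=pd.Index(["p1", "p2"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return MethylationMatrix(data)


def beta_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return MethylationMatrix(
        pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    )


@pytest.fixture()
def make_matrix():
    return beta_matrix
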