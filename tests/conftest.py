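import numpy as np
import pytest

from markerphylo.fixtures import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic study system shared by integration-level tests:
    8 taxa, 12 markers of length 120, a few decoys, one injected paralog."""
    out = tmp_path_factory.mktemp("smallsim")
    spec = SimulationSpec(
        n_taxa=8, n_markers=12, marker_length=120, n_decoys=3,
        paralogs=(("t3", "mk0005"),), seed=7,
    )
    data = simulate_dataset(spec, out)
    data["spec"] = spec
    data["root"] = out
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
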