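import pytest

import angiopatch as ap


@pytest.fixture(scope="session")
def default_ensemble():
    """Fifty default-parameter runs with distinct seeds, computed once.

    Shared by the ensemble-level checks (arrival counts and timing,
    pooled vessel lengths, growth-curve shape).
    """
    return [ap.run_simulation(ap.SimConfig(seed=s)) for s in range(50)]


@pytest.fixture(scope="session")
def default_params():
    return ap.VegfParams()
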