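import warnings

import pytest

from vocrepeat.pipeline import synthetic_compute
from vocrepeat.simulate import SyntheticConfig

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic pipeline run (seed 0), shared across tests."""
    return synthetic_compute(SyntheticConfig(seed=0))


@pytest.fixture()
def config():
    return SyntheticConfig(seed=0)
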