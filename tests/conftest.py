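import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(20260923)


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(text: str, name: str = "in.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
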