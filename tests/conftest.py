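import pytest

from platediv import load_semisolid_counts


@pytest.fixture(scope="session")
def semisolid():
    """Packaged six-experiment counts keyed by (experiment, condition)."""
    return {(r.experiment_id, r.condition): r for r in load_semisolid_counts()}
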