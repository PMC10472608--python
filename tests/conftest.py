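import io

import pytest
from hypothesis import HealthCheck, settings

from immunocost.ledger import parse_ledger, write_ledger
from immunocost.synth import LedgerSpec, default_params, generate_ledger

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def study_config():
    """The complete default parameter fixture of the costing study."""
    return default_params()


@pytest.fixture
def reference_ledger():
    """One-month synthetic ledger hitting the reference monthly breakdown."""
    return generate_ledger(LedgerSpec(months=["2019-01"], seed=11))


def roundtrip(items):
    """Write line items to CSV text and parse them back."""
    buf = io.StringIO()
    write_ledger(items, buf)
    buf.seek(0)
    return parse_ledger(buf)
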