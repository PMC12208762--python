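import pytest

from ankletriage import EXCLUDE_G1_Q6_FLAG, bundled_kb, patient_one, patient_two


@pytest.fixture()
def kb():
    """Bundled knowledge base, strict mode (the default)."""
    return bundled_kb()


@pytest.fixture()
def kb_compat():
    """Bundled knowledge base with the G1.Q6-exclusion compatibility flag on."""
    kb = bundled_kb()
    kb.settings.compatibility_flags[EXCLUDE_G1_Q6_FLAG] = True
    return kb


@pytest.fixture()
def p1():
    return patient_one()


@pytest.fixture()
def p2():
    return patient_two()
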