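import warnings

import pytest
from hypothesis import HealthCheck, settings

from p8barcode.enzymes import builtin_core_enzymes
from p8barcode.fixtures import load_table1

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The bundled 98-taxon survey, loaded once with flags silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return load_table1()


@pytest.fixture(scope="session")
def core_enzymes():
    return builtin_core_enzymes()


@pytest.fixture(scope="session")
def by_taxon(table1):
    return {p.taxon_name: p for p in table1}
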