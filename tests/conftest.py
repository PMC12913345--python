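import dataclasses

import pytest

import parawasp as pw


@pytest.fixture(scope="session")
def nasuta_config():
    return pw.paper_default_config(pw.P_NASUTA)


@pytest.fixture(scope="session")
def coffea_config():
    return pw.paper_default_config(pw.P_COFFEA)


@pytest.fixture(scope="session")
def nasuta_cohort(nasuta_config):
    """Default P. nasuta cohort, seed 7 (all eight temperatures)."""
    return pw.generate_cohort(nasuta_config, seed=7)


@pytest.fixture(scope="session")
def nasuta_25(nasuta_cohort):
    return [r for r in nasuta_cohort if r.temperature == 25.0]


def single_temp_config(base, temp, n):
    """Restrict a default config to one temperature with a chosen cohort size."""
    return dataclasses.replace(base, temperatures=[temp], n_per_temperature=n)
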