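import pytest

from hrdkit.builds import compact_build, default_build


@pytest.fixture(scope="session")
def build():
    """Human-like 22-autosome build."""
    return default_build()


@pytest.fixture(scope="session")
def small_build():
    """Two-chromosome build for fast end-to-end runs."""
    return compact_build(n_chromosomes=2)


@pytest.fixture(scope="session")
def sim_build():
    """Compact build used for the recovery simulation studies."""
    return compact_build()
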