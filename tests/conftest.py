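import pytest

from phagedit.fixtures import FixtureSpec, make_toy_phage
from phagedit.recoding import default_usage_table


@pytest.fixture(scope="session")
def toy():
    """Small all-plus-strand fixture genome."""
    return make_toy_phage(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_mixed():
    """Fixture genome with minus-strand genes."""
    return make_toy_phage(FixtureSpec(seed=3, n_genes=5))


@pytest.fixture(scope="session")
def usage():
    return default_usage_table()


# independent reverse-complement oracle, deliberately not the package's
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@pytest.fixture(scope="session")
def revcomp_oracle():
    return oracle_revcomp
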