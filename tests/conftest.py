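import pytest

from srnameth import (
    LibraryConfig,
    ReferenceSpec,
    build_reference,
    simulate_library,
)


@pytest.fixture(scope="session")
def ref():
    """Default synthetic reference (all locus types, 7 X-cluster motifs)."""
    return build_reference(ReferenceSpec(), seed=11)


@pytest.fixture(scope="session")
def library(ref):
    """Default untreated library with ground truth."""
    return simulate_library(ref, LibraryConfig(), seed=12)
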