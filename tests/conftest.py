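import pytest

from agoassembly import design_primers, select_sites
from agoassembly.fixtures import FixtureSpec, generate_design


@pytest.fixture(scope="session")
def design5():
    """Seeded 5-fragment design at balanced GC, sites finalized."""
    d = generate_design(FixtureSpec(n_fragments=5, gc_target=0.5, seed=7))
    return select_sites(d)


@pytest.fixture(scope="session")
def design8():
    """Seeded 8-fragment design (primer-design acceptance scenario)."""
    d = generate_design(FixtureSpec(n_fragments=8, gc_target=0.5, seed=11))
    return select_sites(d)


@pytest.fixture(scope="session")
def primers5(design5):
    return design_primers(design5)


@pytest.fixture(scope="session")
def primers8(design8):
    return design_primers(design8)
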