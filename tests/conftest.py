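"""Shared fixtures: the worked-example chromosomes used throughout."""

import pytest

from transposort import ChromosomeCycle


@pytest.fixture(scope="session")
def ex_product():
    """9-symbol chromosome used for the applicability / product examples."""
    return ChromosomeCycle([0, 4, 3, 2, 1, 8, 7, 6, 5])


@pytest.fixture(scope="session")
def ex_intersect():
    """Chromosome whose residual mixes even cycles, an oriented 3-cycle and
    an interleaving pair: (0 3)(1 6 8)(2 4)(5 7 9)."""
    return ChromosomeCycle([0, 8, 7, 6, 5, 1, 4, 9, 3, 2])


@pytest.fixture(scope="session")
def ex_components():
    """15-symbol chromosome with two components in its residual."""
    return ChromosomeCycle([0, 6, 5, 3, 2, 1, 8, 7, 4, 9, 14, 13, 12, 11, 10])


@pytest.fixture(scope="session")
def ex_sequence():
    """15-symbol chromosome admitting a printed (4,3)-sequence."""
    return ChromosomeCycle([0, 4, 8, 3, 7, 2, 6, 1, 5, 9, 14, 13, 12, 11, 10])
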