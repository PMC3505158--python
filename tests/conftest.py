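import pytest

from netenrich import Network, RankedGeneList


@pytest.fixture
def triangle() -> Network:
    return Network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star() -> Network:
    """One hub H with three leaves."""
    return Network([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def path3() -> Network:
    return Network([("A", "B"), ("B", "C")])


@pytest.fixture
def abc_ranked() -> RankedGeneList:
    return RankedGeneList("abc", ["A", "B", "C"])
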