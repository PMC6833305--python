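import pytest

from coaltest.msc import SpeciesTreeCU
from coaltest.trees import parse_newick


@pytest.fixture
def quartet_pair():
    return parse_newick("((A,B),(C,D));"), parse_newick("((A,C),(B,D));")


@pytest.fixture
def caterpillar5():
    """Generative 5-taxon caterpillar, all internal branches 1 coalescent unit."""
    return SpeciesTreeCU.from_newick("((((S1,S2):1,S3):1,S4):1,S5);")


@pytest.fixture
def caterpillar5_nni():
    """NNI neighbor of caterpillar5 (S2/S3 exchanged)."""
    return SpeciesTreeCU.from_newick("((((S1,S3):1,S2):1,S4):1,S5);")


@pytest.fixture
def balanced5():
    return SpeciesTreeCU.from_newick("(((S1,S2):1.0,S3):0.5,(S4,S5):0.8);")
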