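import numpy as np
import pytest

from phylodisco.treeops import read_newick


@pytest.fixture
def caterpillar5():
    return read_newick("((((A,B),C),D),E);")


@pytest.fixture
def balanced6():
    """Rooted 6-taxon species tree; shortest internal branch 0.5 cu."""
    t = read_newick("(((A:1,B:1):0.5,(C:1,D:1):0.5):0.5,(E:1,F:1):1.0);")
    t.is_rooted = True
    return t


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq, rate, rng):
    """Independent per-site substitutions at a fixed rate."""
    s = list(seq)
    for i in np.where(rng.random(len(s)) < rate)[0]:
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    return "".join(s)
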