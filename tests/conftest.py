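import numpy as np
import pytest
from hypothesis import settings

# deterministic property testing
settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def four_taxon_tree():
    from paleoclock.timetree import TimeTree

    t = TimeTree.from_newick("((A:100,B:100)ab:200,(C:150,D:150)cd:150)r;")
    t.rates = np.full(t.n_nodes, 1e-3)
    return t
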