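import numpy as np
import pytest

from traitorder import (
    SimConfig,
    TraitTable,
    parse_newick,
    simulate_bm,
    simulate_yule,
    tip_table,
)
from traitorder.fixtures import (
    QUARTET_NEWICK,
    QUARTET_NEWICK_DATED,
    QUARTET_RANKS,
    THREE_TAXON_NEWICK,
)


@pytest.fixture
def quartet():
    """The four-warbler worked example: tree as printed + body-mass ranks."""
    return parse_newick(QUARTET_NEWICK), TraitTable(QUARTET_RANKS)


@pytest.fixture
def quartet_dated():
    return parse_newick(QUARTET_NEWICK_DATED), TraitTable(QUARTET_RANKS)


@pytest.fixture
def three_taxon():
    ranks = {k: QUARTET_RANKS[k] for k in ("virens", "townsendii", "occidentalis")}
    return parse_newick(THREE_TAXON_NEWICK), TraitTable(ranks)


@pytest.fixture
def rng():
    return np.random.default_rng(20170929)


def random_instance(rng, n_tips, sigma2=1.0):
    """A Yule tree with BM traits, the workhorse random test instance."""
    tree = simulate_yule(int(n_tips), rng=rng)
    traits = tip_table(tree, simulate_bm(tree, SimConfig(sigma2=sigma2), rng=rng))
    return tree, traits
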