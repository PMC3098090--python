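import numpy as np
import pytest

from phyloplace import simeval
from phyloplace.models import gtr, jc69
from phyloplace.placement import Placer


@pytest.fixture(scope="session")
def small_fixture():
    """8-taxon, 300-column GTR+Gamma fixture with its placement engine."""
    tree, aln, model, model_text = simeval.make_fixture(8, 300, seed=101)
    return {"tree": tree, "aln": aln, "model": model, "model_text": model_text,
            "placer": Placer(tree, aln, model)}


@pytest.fixture(scope="session")
def tiny_fixture():
    """5-taxon, 120-column fixture for brute-force oracle comparisons."""
    tree, aln, model, model_text = simeval.make_fixture(5, 120, seed=7)
    return {"tree": tree, "aln": aln, "model": model, "model_text": model_text,
            "placer": Placer(tree, aln, model)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_fragment_read(placer, aln, taxon, start, length, name="frag"):
    """Aligned read covering columns [start, start+length) of a leaf row."""
    row = aln.rows[taxon]
    aligned = "-" * start + row[start:start + length] \
        + "-" * (len(row) - start - length)
    return placer.make_read(name, aligned)
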