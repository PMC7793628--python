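import numpy as np
import pytest

from dynhom.matrix import MISSING, MorphMatrix
from dynhom.tree import Node, TimeTree


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with unit-ish branch durations."""
    return TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_matrix(rng, n_taxa, n_char, n_states=2, missing=0.0):
    taxa = [f"t{i}" for i in range(n_taxa)]
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_char):
            if missing and rng.random() < missing:
                row.append(MISSING)
            else:
                row.append(frozenset({int(rng.integers(0, n_states))}))
        cells.append(row)
    return MorphMatrix(taxa=taxa, cells=cells)


def random_time_tree(rng, labels, max_tip_age=0.0, mean_step=1.0):
    from dynhom.tree import build_initial_tree

    ages = {lab: float(rng.uniform(0, max_tip_age)) if max_tip_age else 0.0
            for lab in labels}
    return build_initial_tree(ages, rng=rng, mean_step=mean_step)
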