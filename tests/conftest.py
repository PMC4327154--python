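import numpy as np
import pytest

from ychron.formats import HaplotypeMatrix, Site
from ychron.phylogeny import build_tree
from ychron.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def worked_matrix() -> HaplotypeMatrix:
    """4 samples, 4 compatible sites: derived sets {S1,S2}, {S3,S4}, {S1},
    {S3,S4} — the hand-checkable laminar family used across modules."""
    sites = [Site("Y", i + 1, "A", "G") for i in range(4)]
    calls = np.array([[1, 0, 1, 0],
                      [1, 0, 0, 0],
                      [0, 1, 0, 1],
                      [0, 1, 0, 1]], dtype=np.int8)
    return HaplotypeMatrix(["S1", "S2", "S3", "S4"], sites, calls,
                           np.ones(4, dtype=bool))


@pytest.fixture(scope="session")
def worked_tree(worked_matrix):
    tree, report = build_tree(worked_matrix)
    return tree


@pytest.fixture(scope="session")
def small_dataset():
    """Coalescent dataset at study-condition rates, n=20, seed=1."""
    return simulate_dataset(SimConfig(seed=1, n=20))


def brute_force_min_changes(tree, carriers: set[str],
                            root_state: int | None) -> int:
    """Exhaustive two-state parsimony: enumerate every assignment of
    states to internal nodes and count state changes along branches.
    Independent oracle for the min-change DP; exponential, tiny trees only.
    """
    from itertools import product

    internal = [n.id for n in tree.preorder() if not n.is_tip]
    tips = {(n.sample_id or n.id): n.id for n in tree.tips()}
    tip_state = {nid: (1 if name in carriers else 0)
                 for name, nid in tips.items()}
    best = None
    for assign in product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assign))
        state.update(tip_state)
        if root_state is not None and state[tree.root] != root_state:
            continue
        changes = sum(
            1 for n in tree.preorder()
            if n.parent is not None and state[n.id] != state[n.parent])
        best = changes if best is None else min(best, changes)
    return best
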