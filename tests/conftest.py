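import numpy as np
import pytest

from branchfield import morphology as M


def straight_cable(n_edges: int = 12, step: float = 10.0, radius: float = 0.5,
                   region: str = "dendrite"):
    """Unbranched dendrite of n_edges * step um; root is the first node."""
    nodes = [M.Node(1, None, (0.0, 0.0, 0.0), radius, region)]
    for k in range(n_edges):
        nodes.append(M.Node(k + 2, k + 1, (0.0, (k + 1) * step, 0.0), radius, region))
    return M.Morphology(nodes)


def random_tree(seed: int, n_nodes: int = 50, step: float = 8.0):
    """Random binary-ish dendritic tree with 3-D jitter, root at the origin."""
    rng = np.random.default_rng(seed)
    nodes = [M.Node(1, None, (0.0, 0.0, 0.0), 0.5, "dendrite")]
    tips = [1]
    positions = {1: np.zeros(3)}
    next_id = 2
    while len(nodes) < n_nodes:
        parent = int(rng.choice(tips))
        if rng.random() < 0.25 and len(tips) > 1:
            tips.remove(parent)  # occasionally retire a tip (branch ends)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pos = positions[parent] + direction * step * rng.uniform(0.5, 1.5)
        nodes.append(M.Node(next_id, parent, pos, 0.5, "dendrite"))
        positions[next_id] = pos
        tips.append(next_id)
        next_id += 1
    return M.Morphology(nodes)


@pytest.fixture(scope="session")
def cell0():
    """One synthetic study cell, reused across tests (seed 0)."""
    from branchfield import synth

    return synth.gen_morphology(0)
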