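import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octoscope.io import LeafRoleMap, read_gene_trees

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

DIPLOID_POOL = ["spA", "spB", "spC", "spD", "spE"]


@pytest.fixture
def simple_roles() -> LeafRoleMap:
    return LeafRoleMap(
        {
            "focal1": ("poly", "focal"),
            "focal2": ("poly", "focal"),
            "A": ("spA", "diploid"),
            "B": ("spB", "diploid"),
            "C": ("spC", "diploid"),
            "OG": ("outsp", "outgroup"),
            "IGN": ("ignored_sp", "ignore"),
        }
    )


def random_tree_setup(rng: np.random.Generator, n_leaves: int):
    """Random topology + supports + roles for oracle-equivalence tests.

    Returns (newick string, LeafRoleMap, focal leaf label). Supports are
    missing with probability 0.2, otherwise uniform integers in [0, 100];
    roughly 15% of joins are multifurcating. The first leaf is the focal
    homoeolog; the rest draw roles diploid/focal/outgroup/ignore.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    entries = {"L0": ("poly", "focal")}
    for lab in labels[1:]:
        u = rng.random()
        if u < 0.6:
            entries[lab] = (DIPLOID_POOL[int(rng.integers(len(DIPLOID_POOL)))], "diploid")
        elif u < 0.75:
            entries[lab] = ("poly", "focal")
        elif u < 0.9:
            entries[lab] = ("outsp", "outgroup")
        else:
            entries[lab] = ("junk", "ignore")

    def support() -> str:
        return "" if rng.random() < 0.2 else str(int(rng.integers(0, 101)))

    nodes = list(labels)
    while len(nodes) > 1:
        k = 3 if (len(nodes) > 2 and rng.random() < 0.15) else 2
        picks = rng.choice(len(nodes), size=k, replace=False)
        children = [nodes[i] for i in picks]
        for i in sorted(picks, reverse=True):
            nodes.pop(i)
        nodes.append("(" + ",".join(children) + ")" + support())
    return nodes[0] + ";", LeafRoleMap(entries), "L0"


@pytest.fixture
def random_tree_factory():
    def make(seed: int, n_leaves: int):
        rng = np.random.default_rng(seed)
        newick, roles, focal = random_tree_setup(rng, n_leaves)
        (gt,) = read_gene_trees(newick, roles)
        return gt, roles, focal

    return make
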