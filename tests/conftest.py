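import numpy as np
import pytest
from hypothesis import settings

from pathtrace import parse_newick

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted, possibly multifurcating tree over L1..Ln."""
    pool = [f"L{i + 1}" for i in range(n_leaves)]
    while len(pool) > 1:
        k = min(len(pool), int(rng.integers(2, 5)))
        picks = [pool.pop(int(rng.integers(len(pool)))) for _ in range(k)]
        pool.append("(" + ",".join(picks) + ")")
    return pool[0] + ";"


@pytest.fixture
def random_tree_factory():
    def factory(seed: int, n_leaves: int):
        rng = np.random.default_rng(seed)
        return parse_newick(random_tree_newick(rng, n_leaves))

    return factory
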