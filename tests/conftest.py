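import numpy as np
import pandas as pd
import pytest

from repevo import parse_newick, simulate_yule_tree


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip():
    # balanced topology used by the Dollo worked example
    return parse_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);"
    )


@pytest.fixture(scope="session")
def yule64():
    return simulate_yule_tree(64, seed=20_240_501)


def random_binary_tree(n_tips: int, rng: np.random.Generator):
    """Random rooted binary tree with exponential branch lengths (test oracle
    input; independent of the package's Yule simulator)."""
    labels = [f"T{i}" for i in range(n_tips)]
    frags = [f"{lb}:{rng.exponential(1.0):.6f}" for lb in labels]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a},{b}):{rng.exponential(1.0):.6f}")
    return parse_newick(frags[0] + ";")
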