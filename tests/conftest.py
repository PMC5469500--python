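import numpy as np
import pytest

import ambigem as ag


@pytest.fixture
def chain3():
    return ag.chain_model(3)


@pytest.fixture
def chain3_data_37(chain3):
    """Data 3 and 7 on the first two reactions of a 3-chain: the LAD
    optimum has error 4 at any common flux in [3, 7]."""
    return ag.ReactionData(
        d=np.array([3.0, 7.0, np.nan]), reaction_ids=list(chain3.reaction_ids)
    )


@pytest.fixture
def parallel():
    """Uptake, direct route, two-step route, secretion; core = uptake."""
    model = ag.parallel_paths_model()
    core = ag.CoreSet(core=frozenset({0}), n_reactions=model.n_reactions)
    return model, core


def multi_route_model(k: int) -> ag.MetabolicModel:
    """Uptake -> A, k parallel single-step routes A -> B, B -> out."""
    n = 2 + k
    S = np.zeros((2, n))
    S[0, 0] = 1.0
    for j in range(1, 1 + k):
        S[0, j] = -1.0
        S[1, j] = 1.0
    S[1, n - 1] = -1.0
    return ag.MetabolicModel(
        reaction_ids=[f"R{j + 1}" for j in range(n)],
        metabolite_ids=["A", "B"],
        S=S,
        lb=np.zeros(n),
        ub=np.full(n, 10.0),
        model_id=f"routes{k}",
    )


@pytest.fixture
def two_route():
    model = multi_route_model(2)
    core = ag.CoreSet(core=frozenset({0}), n_reactions=model.n_reactions)
    return model, core


def random_fixture(seed: int, n: int = 12, rev: float = 0.15):
    spec = ag.FixtureSpec(
        topology="random",
        n_reactions=n,
        reversible_fraction=rev,
        core_fraction=0.3,
        data_coverage=0.6,
        seed=seed,
    )
    return ag.make_fixture(spec)
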