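"""Network extraction, dissimilarity search and ensemble enumeration."""

import numpy as np
import pytest

import ambigem as ag
from ambigem.fixtures import _signed_feasible
from tests.conftest import multi_route_model, random_fixture


def test_core_covering_whole_model_adds_nothing(chain3):
    core = ag.CoreSet(core=frozenset(range(3)), n_reactions=3)
    net = ag.corex(ag.split_reversible(chain3), core)
    assert net.Z == 0
    assert np.all(net.include == 1)


def test_parallel_toy_matches_oracle(parallel):
    model, core = parallel
    net = ag.corex(ag.split_reversible(model), core)
    z, sets = ag.brute_force_min_subnetwork(model, core)
    assert net.Z == z == 2
    chosen = frozenset(i for i, v in net.x.items() if v == 1)
    assert chosen in sets


def test_z_lb_relaxes_parsimony(parallel):
    model, core = parallel
    cfg = ag.CorExConfig(z_lb=3)
    net = ag.corex(ag.split_reversible(model), core, cfg)
    assert net.Z == 3
    chosen = frozenset(i for i, v in net.x.items() if v == 1)
    # the size-3 network must itself be consistent at epsilon
    assert _signed_feasible(
        model, set(core.core) | set(chosen), set(core.noncore) - set(chosen),
        cfg.epsilon,
    )


def test_inconsistent_core_diagnosed():
    # core demands flux through a reaction consuming an unproduced metabolite
    S = np.zeros((2, 2))
    S[0, 0] = 1.0
    S[1, 1] = -1.0  # consumes B which nothing produces
    model = ag.MetabolicModel(["R1", "R2"], ["A", "B"], S,
                              np.zeros(2), np.full(2, 10.0))
    core = ag.CoreSet(core=frozenset({1}), n_reactions=2)
    with pytest.raises(ag.InfeasibleError, match="R2"):
        ag.corex(ag.split_reversible(model), core)


def test_altnet_step_finds_symmetric_partner(two_route):
    model, core = two_route
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    alt, mismatches = ag.altnet_step(split, core, net.x, net.Z)
    assert mismatches == 2
    assert alt.Z == net.Z
    assert alt.key() != net.key()


def test_altnet_step_unique_optimum_returns_zero(chain3):
    core = ag.CoreSet(core=frozenset({0}), n_reactions=3)
    split = ag.split_reversible(chain3)
    net = ag.corex(split, core)
    _, mismatches = ag.altnet_step(split, core, net.x, net.Z)
    assert mismatches == 0


def test_enumerate_two_optima(two_route):
    model, core = two_route
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    ensemble = ag.altnet_enumerate(split, core, net, max_iter=20, seed=0)
    assert len(ensemble) == 2
    z, sets = ag.brute_force_min_subnetwork(model, core)
    found = {
        frozenset(i for i, v in nw.x.items() if v == 1)
        for nw in ensemble.networks
    }
    assert found == set(sets)


def test_enumerate_unique_optimum(chain3):
    core = ag.CoreSet(core=frozenset({0}), n_reactions=3)
    split = ag.split_reversible(chain3)
    net = ag.corex(split, core)
    ensemble = ag.altnet_enumerate(split, core, net, max_iter=10, seed=0)
    assert len(ensemble) == 1


def test_enumerate_recovers_four_symmetric_optima():
    model = multi_route_model(4)
    core = ag.CoreSet(core=frozenset({0}), n_reactions=model.n_reactions)
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    z, sets = ag.brute_force_min_subnetwork(model, core)
    assert len(sets) == 4
    found = set()
    for seed in range(5):
        ens = ag.altnet_enumerate(split, core, net, max_iter=50, seed=seed)
        found |= {
            frozenset(i for i, v in nw.x.items() if v == 1)
            for nw in ens.networks
        }
    assert found == set(sets)


def _corda_core(model):
    """Core = uptake & sink; routes partitioned into MC and OT."""
    n = model.n_reactions
    core = frozenset({0, n - 1})
    noncore = sorted(set(range(n)) - core)
    half = len(noncore) // 2
    return ag.CoreSet(
        core=core,
        n_reactions=n,
        mode="corda",
        groups={
            "MC": frozenset(noncore[:half]),
            "NC": frozenset(),
            "OT": frozenset(noncore[half:]),
        },
    )


def test_corda_mode_preserves_group_counts():
    model = multi_route_model(4)
    core = _corda_core(model)
    split = ag.split_reversible(model)
    net = ag.corex(split, ag.CoreSet(core=core.core, n_reactions=model.n_reactions))
    # re-anchor with the corda partition
    anchor = ag.audit_external_network(split, core, net.include)
    assert isinstance(anchor.Z, dict)
    alt, mismatches = ag.altnet_step(split, core, anchor.x, anchor.Z)
    assert alt.Z == anchor.Z  # per-group cardinalities conserved
    if mismatches:
        groups_changed = {
            core.group_of(i)
            for i in anchor.x
            if alt.x[i] != anchor.x[i]
        }
        # swaps happen within a group, never across cardinalities
        assert groups_changed <= {"MC", "NC", "OT"}


def test_audit_round_trip_and_errors(parallel):
    model, core = parallel
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    anchor = ag.audit_external_network(split, core, net.include)
    assert np.array_equal(anchor.include, net.include)
    assert anchor.Z == net.Z

    missing_core = net.include.copy()
    missing_core[next(iter(core.core))] = 0
    with pytest.raises(ag.ValidationError, match="core"):
        ag.audit_external_network(split, core, missing_core)

    superset = np.ones(model.n_reactions, dtype=int)
    audited = ag.audit_external_network(split, core, superset)
    assert audited.Z > net.Z


def test_audit_rejects_inconsistent_network(two_route):
    model, core = two_route
    split = ag.split_reversible(model)
    include = np.zeros(model.n_reactions, dtype=int)
    include[0] = 1  # core alone: no route, no sink -> blocked
    with pytest.raises(ag.InfeasibleError):
        ag.audit_external_network(split, core, include)


@pytest.mark.parametrize("seed", [0, 3])
def test_ensemble_invariants_on_random_fixtures(seed):
    """Every member keeps the core active at epsilon (independent LP
    re-check) and shares the optimal cardinality."""
    model, _, core = random_fixture(seed, n=11)
    if not core.core:
        pytest.skip("fixture has empty core")
    split = ag.split_reversible(model)
    cfg = ag.CorExConfig()
    net = ag.corex(split, core, cfg)
    ensemble = ag.altnet_enumerate(split, core, net, cfg, max_iter=15, seed=1)
    keys = set()
    for nw in ensemble.networks:
        assert nw.Z == net.Z
        keys.add(nw.key())
        chosen = {i for i, v in nw.x.items() if v == 1}
        assert _signed_feasible(
            model, set(core.core) | chosen, set(core.noncore) - chosen,
            cfg.epsilon,
        )
    assert len(keys) == len(ensemble)  # pairwise distinct
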