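"""Binarization, distances, classification, pathway scores and tasks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ambigem as ag
from ambigem.corex import ExtractedNetwork, NetworkEnsemble
from tests.conftest import multi_route_model


def test_binarize_threshold_rule():
    v = np.array([0.0, 1e-7, 2.0])
    assert np.array_equal(ag.binarize(v), np.array([0, 0, 1]))
    assert np.array_equal(ag.binarize(np.zeros(3)), np.zeros(3, dtype=int))


def test_binarize_dedup_rows():
    m = np.array([[1.0, 0.0], [1.0, 1e-9], [0.0, 1.0]])
    assert ag.binarize(m, dedup=True).shape[0] == 2


def test_hamming_basics():
    assert ag.hamming(np.array([1, 0, 1]), np.array([0, 0, 1])) == 1
    assert ag.hamming(np.ones(4), np.ones(4)) == 0
    assert ag.hamming(np.ones(5), np.zeros(5)) == 5
    with pytest.raises(ag.ValidationError):
        ag.hamming(np.ones(3), np.ones(4))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    m=hnp.arrays(np.int8, (4, 9), elements=st.integers(0, 1)),
)
def test_hamming_is_a_metric(m):
    d = {(i, j): ag.hamming(m[i], m[j]) for i in range(4) for j in range(4)}
    for i in range(4):
        assert d[i, i] == 0
        for j in range(4):
            assert d[i, j] == d[j, i]
            for k in range(4):
                assert d[i, k] <= d[i, j] + d[j, k]


def test_hamming_matrix_summary():
    binary = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 1]])
    rep = ag.hamming_matrix(binary, n_noncore=3)
    assert rep.max == 2
    assert rep.mean == pytest.approx((1 + 1 + 2) / 3)
    assert rep.max_pct_noncore == pytest.approx(200 / 3)


def _ensemble_from_rows(rows, noncore):
    networks = [
        ExtractedNetwork(
            include=np.asarray(row),
            x={i: int(row[i]) for i in noncore},
            Z=int(sum(row[i] for i in noncore)),
            witness_flux=np.empty(0),
        )
        for row in rows
    ]
    return NetworkEnsemble(networks, seed=0)


def test_classify_noncore_partitions():
    noncore = [1, 2, 3]
    ens = _ensemble_from_rows([[1, 1, 0, 1], [1, 0, 1, 1]], noncore)
    cls = ag.classify_noncore(ens)
    assert cls.active_set == {3}
    assert cls.variable_set == {1, 2}
    assert cls.inactive_set == frozenset()
    assert dict(cls.frequency) == {1: 0.5, 2: 0.5, 3: 1.0}


def test_classify_single_network_has_no_variable_set():
    ens = _ensemble_from_rows([[1, 1, 0]], [1, 2])
    cls = ag.classify_noncore(ens)
    assert cls.variable_set == frozenset()


def test_classify_matches_column_stats():
    rng = np.random.default_rng(0)
    rows = rng.integers(0, 2, size=(6, 5))
    rows[:, 0] = 1
    noncore = [1, 2, 3, 4]
    cls = ag.classify_noncore(_ensemble_from_rows(rows.tolist(), noncore))
    col_mean = rows[:, noncore].mean(axis=0)
    assert np.allclose(cls.frequency.values, col_mean)


def test_classify_two_route_frequencies(two_route):
    """The two symmetric optima make each route variable at frequency 1/2
    and the sink always included."""
    model, core = two_route
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    ens = ag.altnet_enumerate(split, core, net, max_iter=20, seed=0)
    cls = ag.classify_noncore(ens)
    assert dict(cls.frequency) == {1: 0.5, 2: 0.5, 3: 1.0}


def test_pathway_scores_two_normalizations(chain3):
    chain3.subsystem = ["glycolysis", "glycolysis", ""]
    ens = _ensemble_from_rows([[0, 1, 1], [1, 0, 1]], [0, 1, 2])
    cls = ag.classify_noncore(ens)
    total = ag.pathway_scores(cls, chain3, "total_noncore").table
    per = ag.pathway_scores(cls, chain3, "per_pathway").table
    gly_t = total[total.pathway == "glycolysis"].iloc[0]
    assert gly_t.V_M == 2
    assert gly_t.S_V == pytest.approx(2 / 3)
    gly_p = per[per.pathway == "glycolysis"].iloc[0]
    assert gly_p.S_V == pytest.approx(1.0)
    assert "unassigned" in set(total.pathway)


def test_run_tasks_pass_and_fail(two_route):
    model, core = two_route
    suite = ag.TaskSuite(
        tasks=[ag.MetabolicTask("make_B", uptakes={"R1": (0.0, 10.0)},
                                product="R4", min_flux=1.0)]
    )
    res = ag.run_tasks(model, suite)
    assert res.fraction_passed == 1.0
    # remove both routes: the task must fail
    sub = model.subset([0, 3])
    res2 = ag.run_tasks(sub, suite)
    assert res2.fraction_passed == 0.0


def test_run_tasks_validation_and_empty_suite(chain3):
    bad = ag.TaskSuite(
        tasks=[ag.MetabolicTask("t", uptakes={"NOPE": (0, 1)}, product="R3")]
    )
    with pytest.raises(ag.ValidationError, match="NOPE"):
        ag.run_tasks(chain3, bad)
    with pytest.warns(UserWarning):
        res = ag.run_tasks(chain3, ag.TaskSuite(tasks=[]))
    assert res.fraction_passed == 1.0


def test_task_suite_yaml_round_trip(tmp_path, chain3):
    (tmp_path / "suite.yaml").write_text(
        "tasks:\n"
        "  - id: demo\n"
        "    uptakes:\n"
        "      R1: [0.0, 10.0]\n"
        "    product: R3\n"
        "    min_flux: 0.5\n"
    )
    suite = ag.TaskSuite.from_file(tmp_path / "suite.yaml")
    assert suite.tasks[0].task_id == "demo"
    res = ag.run_tasks(chain3, suite)
    assert res.all_passed()


def test_task_filter_never_enlarges_variable_set():
    model = multi_route_model(2)
    core = ag.CoreSet(core=frozenset({0}), n_reactions=model.n_reactions)
    split = ag.split_reversible(model)
    net = ag.corex(split, core)
    ens = ag.altnet_enumerate(split, core, net, max_iter=20, seed=0)
    before = len(ag.classify_noncore(ens).variable_set)
    suite = ag.TaskSuite(
        tasks=[ag.MetabolicTask("make_B", uptakes={"R1": (0.0, 10.0)},
                                product="R4", min_flux=1.0)]
    )
    kept = ag.filter_ensemble_by_tasks(ens, model, suite)
    assert 1 <= len(kept) <= len(ens)
    after = len(ag.classify_noncore(kept).variable_set) if len(kept) else 0
    assert after <= before
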