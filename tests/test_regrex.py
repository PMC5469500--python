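"""LAD flux fitting, lambda selection, and alternative-optima sampling."""

import numpy as np
import pytest

import ambigem as ag
from ambigem.regrex import _aos_iterate
from tests.conftest import multi_route_model, random_fixture


def _fit(model, data, lam=0.0):
    split = ag.split_reversible(model)
    problem = ag.RegrExProblem(split, data, lam=lam)
    return problem, ag.regrex_lad(problem)


def test_reachable_data_gives_zero_error(chain3):
    data = ag.ReactionData(
        d=np.array([3.0, np.nan, np.nan]), reaction_ids=list(chain3.reaction_ids)
    )
    _, sol = _fit(chain3, data)
    assert sol.error_norm == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(sol.v_opt, 3.0, atol=1e-7)


def test_conflicting_data_error_norm(chain3, chain3_data_37):
    """min |v-3| + |v-7| over a common chain flux v equals 4, attained on
    [3, 7] (1-D scan oracle)."""
    scan = min(abs(v - 3) + abs(v - 7) for v in np.linspace(0, 10, 2001))
    _, sol = _fit(chain3, chain3_data_37)
    assert sol.error_norm == pytest.approx(scan, abs=1e-9)
    assert sol.error_norm == pytest.approx(4.0, abs=1e-9)
    v = sol.v_opt
    assert np.allclose(v, v[0], atol=1e-7)
    assert 3.0 - 1e-7 <= v[0] <= 7.0 + 1e-7


def test_full_shrinkage_at_lambda_one(chain3):
    """With max-scaled data, lambda = 1 shrinks every flux to zero."""
    data = ag.ReactionData(
        d=np.array([0.5, 0.3, np.nan]), reaction_ids=list(chain3.reaction_ids)
    )
    _, sol = _fit(chain3, data, lam=1.0)
    assert np.max(np.abs(sol.v_opt)) < 1e-9
    assert sol.error_norm == pytest.approx(0.8, abs=1e-9)


def test_error_complementarity_and_balance(chain3, chain3_data_37):
    _, sol = _fit(chain3, chain3_data_37)
    bounded = chain3_data_37.data_bounded
    prod = sol.eps_plus[bounded] * sol.eps_minus[bounded]
    assert np.all(prod < 1e-9)
    # eps+ - eps- reproduces d - |v|
    resid = chain3_data_37.d[bounded] - np.abs(sol.v_opt[bounded])
    assert np.allclose(sol.eps_plus[bounded] - sol.eps_minus[bounded], resid,
                       atol=1e-7)


def test_select_lambda_singleton(chain3):
    data = ag.ReactionData(
        d=np.array([0.5, 0.3, np.nan]), reaction_ids=list(chain3.reaction_ids)
    )
    lam, sols = ag.select_lambda(chain3, data, [0.0])
    assert lam == 0.0
    assert set(sols) == {0.0}


def test_select_lambda_skips_degenerate_zero_vector(chain3):
    """lambda = 1 zeroes all fluxes -> correlation undefined -> scored -inf."""
    data = ag.ReactionData(
        d=np.array([0.5, 0.3, np.nan]), reaction_ids=list(chain3.reaction_ids)
    )
    lam, sols = ag.select_lambda(chain3, data, [0.0, 1.0])
    assert lam == 0.0
    assert sols[1.0].l1_norm == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_l1_norm_monotone_in_lambda(seed):
    model, data, _ = random_fixture(seed)
    split = ag.split_reversible(model)
    l1_prev = np.inf
    for lam in [0.0, 0.1, 0.3, 0.5, 1.0]:
        sol = ag.regrex_lad(ag.RegrExProblem(split, data, lam=lam))
        assert sol.l1_norm <= l1_prev + 1e-6
        l1_prev = sol.l1_norm


def test_aos_zero_distance_draw_returns_optimum(chain3, chain3_data_37):
    problem, sol = _fit(chain3, chain3_data_37)
    spec = ag.AOS_SPEC
    slack = max(spec.feasibility_tol, 1e-7)
    row = _aos_iterate(
        problem, sol, sol.v_opt,
        spec,
        slack * max(1.0, sol.weighted_error),
        slack * max(1.0, sol.l1_norm),
    )
    assert np.allclose(row, sol.v_opt, atol=1e-5)


def test_aos_preserves_norms_and_oracle_span(chain3, chain3_data_37):
    problem, sol = _fit(chain3, chain3_data_37)
    sample = ag.regrex_aos(problem, sol, n=40, seed=11)
    bounded = chain3_data_37.data_bounded
    for row in sample.matrix:
        err = np.abs(np.abs(row[bounded]) - chain3_data_37.d[bounded]).sum()
        assert err == pytest.approx(sol.error_norm, abs=1e-5)
        assert np.abs(row).sum() == pytest.approx(sol.l1_norm, abs=1e-5)
    vmin, vmax = ag.brute_force_aos_extrema(chain3, chain3_data_37, sol)
    assert np.all(sample.matrix.min(axis=0) >= vmin - 1e-5)
    assert np.all(sample.matrix.max(axis=0) <= vmax + 1e-5)


def test_aos_varies_over_degenerate_routes():
    """Two parallel single-step routes split a fixed total flux freely: the
    alternative optima form a segment the sampler must spread over."""
    model = multi_route_model(2)  # R1 -> A; R2,R3: A -> B; R4: B ->
    data = ag.ReactionData(
        d=np.array([6.0, np.nan, np.nan, 6.0]),
        reaction_ids=list(model.reaction_ids),
    )
    split = ag.split_reversible(model)
    problem = ag.RegrExProblem(split, data)
    sol = ag.regrex_lad(problem)
    assert sol.error_norm == pytest.approx(0.0, abs=1e-7)
    sample = ag.regrex_aos(problem, sol, n=60, seed=4)
    r2 = sample.matrix[:, 1]
    vmin, vmax = ag.brute_force_aos_extrema(model, data, sol)
    assert vmax[1] - vmin[1] == pytest.approx(6.0, abs=1e-4)
    # samples cover most of the oracle span
    assert (r2.max() - r2.min()) >= 0.8 * (vmax[1] - vmin[1])


def test_aos_reversible_sign_freedom():
    """A data-orphan boundary reaction keeps |v| (L1 budget) but may flip
    sign across alternative optima."""
    model, data, _ = ag.make_fixture(ag.FixtureSpec(topology="free_boundary"))
    split = ag.split_reversible(model)
    problem = ag.RegrExProblem(split, data)
    sol = ag.regrex_lad(problem)
    sample = ag.regrex_aos(problem, sol, n=30, seed=5)
    # data-bounded pair pinned at d
    assert np.allclose(sample.matrix[:, 0], 0.8, atol=1e-5)
    assert np.allclose(sample.matrix[:, 1], 0.8, atol=1e-5)
    # |v3| pinned at its optimal magnitude
    assert np.allclose(np.abs(sample.matrix[:, 2]), abs(sol.v_opt[2]), atol=1e-5)


def test_aos_reproducible(chain3, chain3_data_37):
    problem, sol = _fit(chain3, chain3_data_37)
    s1 = ag.regrex_aos(problem, sol, n=10, seed=9)
    s2 = ag.regrex_aos(problem, sol, n=10, seed=9)
    assert np.array_equal(s1.matrix, s2.matrix)
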