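"""L1-regularized flux fitting and sampling of its alternative optima.

The fitting step finds a steady-state flux distribution closest (in the
least-absolute-deviations sense) to expression-derived reaction scores:

    min  w^T (e+ + e-) + lambda * ||v||_1

over non-negative split fluxes, where e = d - |v| on the data-bounded set
R_D.  Reversible reactions are split into forward/backward directions and
a binary selector per reversible reaction makes them mutually exclusive
(x = 1 selects the backward direction).

The alternative-optima sampler then repeatedly draws a random point inside
the FVA box, flips the frame of reversible reactions whose draw is
negative (equivalent to negating the matching stoichiometric columns), and
finds the flux vector closest (L1) to the draw among all vectors that keep
both the optimal data distance and the optimal L1 norm.  The empirical
distribution of those samples quantifies how underdetermined each reaction
flux is at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InfeasibleError, SolverError, ValidationError
from .model import MetabolicModel, ReactionData, SplitModel, split_reversible
from .optcore import AOS_SPEC, LinearProgram, SolverSpec, Status
from .variability import FluxRange, FluxSample, fva

log = logging.getLogger(__name__)


@dataclass
class RegrExProblem:
    """A data-integration problem: split model, reaction data, weights."""

    split: SplitModel
    data: ReactionData
    lam: float = 0.0
    w: np.ndarray | None = None  # per-reaction error weights (default ones)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        n = self.split.origin.n_reactions
        if self.w is None:
            self.w = np.ones(n)
        else:
            self.w = np.asarray(self.w, dtype=float)
            if self.w.shape != (n,) or np.any(self.w <= 0):
                raise ValidationError("w must be positive, one weight per reaction")
        if len(self.data.reaction_ids) != n:
            raise ValidationError("data does not match the model")


@dataclass
class RegrExSolution:
    """An optimal fit: fluxes, error decomposition and norms."""

    v_opt: np.ndarray          # original orientation
    v_split: np.ndarray        # (v_irr; v_for; v_back) >= 0
    eps_plus: np.ndarray       # per-reaction, NaN on data orphans
    eps_minus: np.ndarray
    x: np.ndarray              # direction selector per reversible (1 = backward)
    objective: float
    error_norm: float          # sum of (e+ + e-) over R_D, unweighted
    weighted_error: float      # w^T (e+ + e-), the objective's data term
    l1_norm: float             # ||v||_1 = sum of split fluxes
    lam: float


class _Op1Vars:
    """Name registry for one instantiation of the fitting constraint system."""

    def __init__(self) -> None:
        self.v_irr: list[str] = []
        self.v_for: list[str] = []
        self.v_back: list[str] = []
        self.x: list[str] = []
        self.err: list[tuple[str, float]] = []  # (var name, weight) pairs
        self.err_plain: list[str] = []          # unweighted listing


def _build_fit_system(
    lp: LinearProgram,
    problem: RegrExProblem,
    flip: np.ndarray | None = None,
) -> _Op1Vars:
    """Install the split-flux fitting constraints into ``lp``.

    ``flip`` (boolean per reversible reaction) exchanges the roles of the
    forward/backward columns — the sign-flip treatment the sampler applies
    to reversible reactions drawn negative.  All constraints are symmetric
    under this exchange, so the same builder serves both the fit and the
    sampler.
    """
    split = problem.split
    data = problem.data
    n_irr, n_rev = split.n_irr, split.n_rev
    if flip is None:
        flip = np.zeros(n_rev, dtype=bool)
    bounded = set(data.data_bounded.tolist())
    V = _Op1Vars()

    for k in range(n_irr):
        i = split.irr_idx[k]
        V.v_irr.append(
            lp.add_var(f"vI{k}", lb=split.lb_ext[k], ub=split.ub_ext[k])
        )
    ub_for_all = split.ub_ext[n_irr : n_irr + n_rev]
    ub_back_all = split.ub_ext[n_irr + n_rev :]
    for k in range(n_rev):
        ubF = float(ub_back_all[k] if flip[k] else ub_for_all[k])
        ubB = float(ub_for_all[k] if flip[k] else ub_back_all[k])
        V.v_for.append(lp.add_var(f"vF{k}", lb=0.0, ub=ubF))
        V.v_back.append(lp.add_var(f"vB{k}", lb=0.0, ub=ubB))
        V.x.append(lp.add_var(f"x{k}", binary=True))

    # 1. mass balance over the (possibly frame-flipped) split matrix
    S = split.origin.S
    for row in range(split.origin.n_metabolites):
        coeffs: dict[str, float] = {}
        for k in range(n_irr):
            c = S[row, split.irr_idx[k]]
            if c:
                coeffs[V.v_irr[k]] = c
        for k in range(n_rev):
            c = S[row, split.rev_idx[k]]
            if c:
                sgn = -1.0 if flip[k] else 1.0
                coeffs[V.v_for[k]] = sgn * c
                coeffs[V.v_back[k]] = -sgn * c
        if coeffs:
            lp.add_eq(coeffs, 0.0)

    # 2-4. error balances on the data-bounded set
    for k in range(n_irr):
        i = split.irr_idx[k]
        if i not in bounded:
            continue
        d = data.value(i)
        ep = lp.add_var(f"epI{k}")
        em = lp.add_var(f"emI{k}")
        lp.add_eq({V.v_irr[k]: 1.0, ep: 1.0, em: -1.0}, d)
        wt = float(problem.w[i])
        V.err += [(ep, wt), (em, wt)]
        V.err_plain += [ep, em]
    for k in range(n_rev):
        i = split.rev_idx[k]
        if i not in bounded:
            continue
        d = data.value(i)
        wt = float(problem.w[i])
        epf = lp.add_var(f"epF{k}")
        emf = lp.add_var(f"emF{k}")
        epb = lp.add_var(f"epB{k}")
        emb = lp.add_var(f"emB{k}")
        # forward error matches d unless the backward direction is selected
        lp.add_eq({V.v_for[k]: 1.0, epf: 1.0, emf: -1.0, V.x[k]: d}, d)
        lp.add_eq({V.v_back[k]: 1.0, epb: 1.0, emb: -1.0, V.x[k]: -d}, 0.0)
        V.err += [(epf, wt), (emf, wt), (epb, wt), (emb, wt)]
        V.err_plain += [epf, emf, epb, emb]

    # 6-9. direction exclusivity via x (x = 1 shuts the forward column)
    for k in range(n_rev):
        ubF = lp._ub[lp._pos[V.v_for[k]]]
        ubB = lp._ub[lp._pos[V.v_back[k]]]
        if np.isfinite(ubF) and ubF > 0:
            lp.add_constr({V.v_for[k]: 1.0, V.x[k]: ubF}, ub=ubF)
        if np.isfinite(ubB) and ubB > 0:
            lp.add_constr({V.v_back[k]: 1.0, V.x[k]: -ubB}, ub=0.0)
    return V


def _extract_solution(
    problem: RegrExProblem,
    V: _Op1Vars,
    result,
    flip: np.ndarray | None = None,
) -> RegrExSolution:
    split = problem.split
    n = split.origin.n_reactions
    if flip is None:
        flip = np.zeros(split.n_rev, dtype=bool)
    v_irr = result.values(V.v_irr) if V.v_irr else np.empty(0)
    v_for = result.values(V.v_for) if V.v_for else np.empty(0)
    v_back = result.values(V.v_back) if V.v_back else np.empty(0)
    x = result.values(V.x) if V.x else np.empty(0)

    v = np.zeros(n)
    v[split.irr_idx] = v_irr
    signed = v_for - v_back
    signed[flip] = -signed[flip]
    v[split.rev_idx] = signed

    # canonical split layout (original frame)
    v_split = np.zeros(split.n_cols)
    v_split[: split.n_irr] = v_irr
    orig_for = np.where(flip, v_back, v_for)
    orig_back = np.where(flip, v_for, v_back)
    v_split[split.n_irr : split.n_irr + split.n_rev] = orig_for
    v_split[split.n_irr + split.n_rev :] = orig_back

    eps_plus = np.full(n, np.nan)
    eps_minus = np.full(n, np.nan)
    err_vals = {name: result[name] for name in V.err_plain}
    for k in range(split.n_irr):
        i = split.irr_idx[k]
        if f"epI{k}" in err_vals:
            eps_plus[i] = err_vals[f"epI{k}"]
            eps_minus[i] = err_vals[f"emI{k}"]
    for k in range(split.n_rev):
        i = split.rev_idx[k]
        if f"epF{k}" in err_vals:
            eps_plus[i] = err_vals[f"epF{k}"] + err_vals[f"epB{k}"]
            eps_minus[i] = err_vals[f"emF{k}"] + err_vals[f"emB{k}"]

    error_norm = float(sum(err_vals.values()))
    weighted = float(sum(err_vals[nm] * wt for nm, wt in V.err))
    l1 = float(v_split.sum())
    return RegrExSolution(
        v_opt=v,
        v_split=v_split,
        eps_plus=eps_plus,
        eps_minus=eps_minus,
        x=x,
        objective=float(result.objective),
        error_norm=error_norm,
        weighted_error=weighted,
        l1_norm=l1,
        lam=problem.lam,
    )


def regrex_lad(
    problem: RegrExProblem, spec: SolverSpec | None = None
) -> RegrExSolution:
    """Solve the LAD fitting MILP to certified optimality."""
    spec = spec or SolverSpec()
    lp = LinearProgram("regrex_lad")
    V = _build_fit_system(lp, problem)
    obj = {name: wt for name, wt in V.err}
    if problem.lam > 0:
        for name in V.v_irr + V.v_for + V.v_back:
            obj[name] = obj.get(name, 0.0) + problem.lam
    if not obj:
        # no data and lambda = 0: any feasible point is optimal
        obj = {V.v_irr[0] if V.v_irr else V.v_for[0]: 0.0}
    lp.set_objective(obj, "min")
    res = lp.solve(spec)
    if res.status == Status.INFEASIBLE:
        raise InfeasibleError("fitting problem infeasible: model inconsistent")
    if res.status == Status.UNBOUNDED:
        raise InfeasibleError("fitting problem unbounded: missing flux bounds")
    if res.status != Status.OPTIMAL:
        raise SolverError(f"fitting solve ended with status {res.status}")
    return _extract_solution(problem, V, res)


def select_lambda(
    model: MetabolicModel,
    data: ReactionData,
    grid: list[float],
    spec: SolverSpec | None = None,
    w: np.ndarray | None = None,
) -> tuple[float, dict[float, RegrExSolution]]:
    """Fit over a lambda grid; pick the lambda maximizing the Pearson
    correlation between data and |flux| on R_D (ties -> smallest lambda)."""
    if not grid:
        raise ValidationError("lambda grid must be non-empty")
    split = split_reversible(model)
    bounded = data.data_bounded
    solutions: dict[float, RegrExSolution] = {}
    best_lam, best_corr = None, -np.inf
    for lam in sorted(grid):
        sol = regrex_lad(RegrExProblem(split, data, lam=lam, w=w), spec)
        solutions[lam] = sol
        d = data.d[bounded]
        av = np.abs(sol.v_opt[bounded])
        if bounded.size < 2 or np.ptp(av) == 0 or np.ptp(d) == 0:
            corr = -np.inf
            log.warning(
                "lambda=%g: correlation undefined (constant vector); scored -inf",
                lam,
            )
        else:
            corr = float(stats.pearsonr(d, av).statistic)
        if corr > best_corr:
            best_lam, best_corr = lam, corr
    if best_lam is None:  # every grid point undefined: fall back to smallest
        best_lam = min(grid)
    return best_lam, solutions


def regrex_aos(
    problem: RegrExProblem,
    solution: RegrExSolution,
    n: int,
    seed: int = 0,
    spec: SolverSpec | None = None,
    ranges: FluxRange | None = None,
) -> FluxSample:
    """Sample alternative optimal flux distributions of a previous fit.

    Every sample keeps the optimal (weighted) data distance and the optimal
    L1 norm; among such vectors, the one closest (L1) to a uniform random
    point in the FVA box is returned.  Identical optima appearing for
    different draws are kept: the entropy estimator downstream needs the
    empirical distribution, not distinct points.
    """
    spec = spec or AOS_SPEC
    split = problem.split
    model = split.origin
    ranges = ranges or fva(model)
    rng = np.random.default_rng(seed)
    rows = np.empty((n, model.n_reactions))
    slack_err = max(spec.feasibility_tol, 1e-7) * max(1.0, solution.weighted_error)
    slack_l1 = max(spec.feasibility_tol, 1e-7) * max(1.0, solution.l1_norm)
    for it in range(n):
        v_rand = rng.uniform(ranges.minimum, ranges.maximum)
        rows[it] = _aos_iterate(
            problem, solution, v_rand, spec, slack_err, slack_l1
        )
    return FluxSample(
        matrix=rows,
        reaction_ids=list(model.reaction_ids),
        seed=seed,
        provenance="regrex_aos",
        lam=problem.lam,
    )


def _aos_iterate(
    problem: RegrExProblem,
    solution: RegrExSolution,
    v_rand: np.ndarray,
    spec: SolverSpec,
    slack_err: float,
    slack_l1: float,
) -> np.ndarray:
    split = problem.split
    flip = v_rand[split.rev_idx] < 0
    r_irr = np.maximum(v_rand[split.irr_idx], 0.0)
    r_rev = np.abs(v_rand[split.rev_idx])

    lp = LinearProgram("regrex_aos")
    V = _build_fit_system(lp, problem, flip=flip)

    # 10-11: stay on the optimum face (two-sided with numeric slack)
    lp.add_eq(dict(V.err), solution.weighted_error, slack=slack_err)
    lp.add_eq(
        {name: 1.0 for name in V.v_irr + V.v_for + V.v_back},
        solution.l1_norm,
        slack=slack_l1,
    )

    # 12-14: L1 distance to the draw
    obj: dict[str, float] = {}
    for k in range(split.n_irr):
        dp = lp.add_var(f"dpI{k}")
        dm = lp.add_var(f"dmI{k}")
        lp.add_eq({V.v_irr[k]: 1.0, dp: 1.0, dm: -1.0}, float(r_irr[k]))
        obj[dp] = 1.0
        obj[dm] = 1.0
    for k in range(split.n_rev):
        r = float(r_rev[k])
        dpf = lp.add_var(f"dpF{k}")
        dmf = lp.add_var(f"dmF{k}")
        db = lp.add_var(f"dB{k}")
        # x=0 (draw direction): delta_for = r - v_for, delta_back = 0
        # x=1 (anti-draw):     delta_for = 0,         delta_back = r + v_back
        lp.add_eq({V.v_for[k]: 1.0, dpf: 1.0, dmf: -1.0, V.x[k]: r}, r)
        lp.add_eq({db: 1.0, V.v_back[k]: -1.0, V.x[k]: -r}, 0.0)
        obj[dpf] = 1.0
        obj[dmf] = 1.0
        obj[db] = 1.0
    lp.set_objective(obj, "min")
    res = lp.solve(spec)
    if res.status != Status.OPTIMAL:
        raise InfeasibleError(
            "alternative-optima subproblem not optimal "
            f"(status {res.status}); the previous optimum must be feasible"
        )
    sol = _extract_solution(problem, V, res, flip=flip)
    return sol.v_opt
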