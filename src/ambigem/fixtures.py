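"""Synthetic test models, planted cores and brute-force oracles.

Every generated model is consistent by construction (each reaction sits on
a directed uptake-to-secretion path), so model reduction leaves it
unchanged.  The brute-force oracles re-derive, by exhaustive enumeration
over plain LPs, the quantities the MILP machinery computes; they share no
constraint-builder code with the main implementation, so agreement between
the two is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .corex import CoreSet
from .exceptions import InfeasibleError, ValidationError
from .expression import map_expression_to_reactions
from .model import MetabolicModel, ReactionData
from .regrex import RegrExSolution

_MAX_P = 14          # exhaustive subset scan cap
_MAX_REV_ENUM = 12   # sign-pattern enumeration cap


@dataclass
class FixtureSpec:
    topology: str = "chain"  # chain | parallel_paths | free_boundary | random
    n_reactions: int = 3
    reversible_fraction: float = 0.0
    core_fraction: float = 0.3
    data_coverage: float = 0.5
    seed: int = 0
    bound: float = 10.0

    def __post_init__(self) -> None:
        for name in ("reversible_fraction", "core_fraction", "data_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_reactions < 1:
            raise ValidationError("need at least one reaction")


def make_fixture(
    spec: FixtureSpec,
) -> tuple[MetabolicModel, ReactionData, CoreSet]:
    """Build a consistent toy model with planted data and core set."""
    if spec.topology == "chain":
        model = chain_model(spec.n_reactions, bound=spec.bound)
    elif spec.topology == "parallel_paths":
        model = parallel_paths_model(bound=spec.bound)
    elif spec.topology == "free_boundary":
        return _free_boundary(spec)
    elif spec.topology == "random":
        model = random_model(spec)
    else:
        raise ValidationError(f"unknown topology {spec.topology!r}")
    data, core = _plant_data_and_core(model, spec)
    return model, data, core


def chain_model(n: int, bound: float = 10.0, prefix: str = "R") -> MetabolicModel:
    """Linear pathway: uptake -> M1 -> ... -> M_{n-1} -> secretion."""
    if n < 1:
        raise ValidationError("chain needs >= 1 reaction")
    mets = [f"M{i}" for i in range(1, n)]
    S = np.zeros((len(mets), n))
    for j in range(n):
        if j > 0:
            S[j - 1, j] = -1.0
        if j < n - 1:
            S[j, j] = 1.0
    return MetabolicModel(
        reaction_ids=[f"{prefix}{j + 1}" for j in range(n)],
        metabolite_ids=mets,
        S=S,
        lb=np.zeros(n),
        ub=np.full(n, bound),
        model_id=f"chain{n}",
    )


def parallel_paths_model(bound: float = 10.0) -> MetabolicModel:
    """Uptake ->A, two routes A=>B (direct R2, or R3+R4 via C), B-> out."""
    mets = ["A", "B", "C"]
    rxns = ["R1", "R2", "R3", "R4", "R5"]
    S = np.zeros((3, 5))
    S[0, 0] = 1.0                      # R1: -> A
    S[0, 1], S[1, 1] = -1.0, 1.0       # R2: A -> B
    S[0, 2], S[2, 2] = -1.0, 1.0       # R3: A -> C
    S[2, 3], S[1, 3] = -1.0, 1.0       # R4: C -> B
    S[1, 4] = -1.0                     # R5: B ->
    return MetabolicModel(
        reaction_ids=rxns,
        metabolite_ids=mets,
        S=S,
        lb=np.zeros(5),
        ub=np.full(5, bound),
        model_id="parallel_paths",
    )


def _free_boundary(spec: FixtureSpec) -> tuple[MetabolicModel, ReactionData, CoreSet]:
    """Three reactions, data on the first two only; the third is a
    data-orphan boundary reaction whose flux is unconstrained by mass
    balance and therefore free to vary across the alternative optima."""
    S = np.zeros((1, 3))
    S[0, 0] = 1.0   # v1: -> A
    S[0, 1] = -1.0  # v2: A ->
    # v3: boundary conversion of external species (empty column), reversible
    model = MetabolicModel(
        reaction_ids=["v1", "v2", "v3"],
        metabolite_ids=["A"],
        S=S,
        lb=np.array([0.0, 0.0, -spec.bound]),
        ub=np.full(3, spec.bound),
        model_id="free_boundary",
    )
    data = ReactionData(
        d=np.array([0.8, 0.8, np.nan]), reaction_ids=list(model.reaction_ids)
    )
    core = CoreSet(core=frozenset({0, 1}), n_reactions=3)
    return model, data, core


def random_model(spec: FixtureSpec) -> MetabolicModel:
    """Random consistent topology: a backbone chain plus branch pairs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reactions
    n_backbone = min(n, max(3, n // 2))
    base = chain_model(n_backbone, bound=spec.bound)
    rxn_ids = list(base.reaction_ids)
    met_ids = list(base.metabolite_ids)
    # represent S as a list of (row, value) per column to allow row growth
    col_entries = [
        [(i, base.S[i, j]) for i in range(len(base.metabolite_ids)) if base.S[i, j]]
        for j in range(n_backbone)
    ]
    n_extra = n - n_backbone
    b = 0
    while n_extra > 0:
        if n_extra >= 2 and met_ids:
            src = int(rng.integers(0, len(met_ids)))
            new_met = f"B{b}"
            b += 1
            met_idx = len(met_ids)
            met_ids.append(new_met)
            col_entries.append([(src, -1.0), (met_idx, 1.0)])  # branch in
            rxn_ids.append(f"BR{b}a")
            col_entries.append([(met_idx, -1.0)])              # branch out
            rxn_ids.append(f"BR{b}b")
            n_extra -= 2
        else:
            # duplicate a backbone internal step (parallel route)
            j = int(rng.integers(0, n_backbone))
            col_entries.append(list(col_entries[j]))
            rxn_ids.append(f"DUP{len(rxn_ids)}")
            n_extra -= 1
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, entries in enumerate(col_entries):
        for i, val in entries:
            S[i, j] = val
    lb = np.zeros(len(rxn_ids))
    ub = np.full(len(rxn_ids), spec.bound)
    # mark a seeded subset of non-uptake reactions reversible
    n_rev = int(round(spec.reversible_fraction * len(rxn_ids)))
    candidates = np.arange(1, len(rxn_ids))
    if n_rev > 0 and candidates.size:
        chosen = rng.choice(candidates, size=min(n_rev, candidates.size), replace=False)
        lb[chosen] = -spec.bound
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lb=lb,
        ub=ub,
        model_id=f"random{spec.seed}",
    )


def _plant_data_and_core(
    model: MetabolicModel, spec: FixtureSpec
) -> tuple[ReactionData, CoreSet]:
    rng = np.random.default_rng(spec.seed + 1)
    n = model.n_reactions
    n_data = int(round(spec.data_coverage * n))
    covered = (
        rng.choice(n, size=n_data, replace=False) if n_data else np.array([], int)
    )
    gpr = [""] * n
    expr: dict[str, float] = {}
    for j in covered:
        gene = f"g{j}"
        gpr[j] = gene
        expr[gene] = float(rng.uniform(0.05, 1.0))
    model.gpr = gpr
    if expr:
        data = map_expression_to_reactions(model, expr)
    else:
        data = ReactionData(d=np.full(n, np.nan), reaction_ids=list(model.reaction_ids))
    n_core = int(round(spec.core_fraction * n))
    bounded = data.data_bounded
    if n_core and bounded.size:
        order = bounded[np.argsort(-data.d[bounded], kind="stable")]
        core = frozenset(int(i) for i in order[:n_core])
    else:
        core = frozenset()
    return data, CoreSet(core=core, n_reactions=n)


# -- brute-force oracles ----------------------------------------------------


def _signed_feasible(
    model: MetabolicModel,
    included: set[int],
    excluded: set[int],
    eps: float,
) -> bool:
    """LP feasibility of 'included active at eps, excluded zero' by
    enumerating the direction of every included reversible reaction."""
    rev_inc = [i for i in included if model.reversible[i]]
    if len(rev_inc) > _MAX_REV_ENUM:
        raise ValidationError("too many reversible reactions for enumeration")
    A = sparse.csr_matrix(model.S)
    b = np.zeros(model.n_metabolites)
    for signs in itertools.product((1, -1), repeat=len(rev_inc)):
        lb = model.lb.copy()
        ub = model.ub.copy()
        ok = True
        for i in excluded:
            lb[i] = ub[i] = 0.0
        for i in included:
            if i in rev_inc:
                continue
            if ub[i] < eps:
                ok = False
                break
            lb[i] = max(lb[i], eps)
        if not ok:
            continue
        for i, s in zip(rev_inc, signs):
            if s > 0:
                if ub[i] < eps:
                    ok = False
                    break
                lb[i] = max(lb[i], eps)
            else:
                if lb[i] > -eps:
                    ok = False
                    break
                ub[i] = min(ub[i], -eps)
        if not ok:
            continue
        res = linprog(
            np.zeros(model.n_reactions),
            A_eq=A,
            b_eq=b,
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if res.status == 0:
            return True
    return False


def brute_force_min_subnetwork(
    model: MetabolicModel,
    core: CoreSet,
    eps: float = 1e-4,
) -> tuple[int, list[frozenset[int]]]:
    """Exhaustively find the minimum number of non-core additions keeping
    the core active at eps, and every optimal addition set."""
    P = sorted(core.noncore)
    if len(P) > _MAX_P:
        raise ValidationError(f"|P| = {len(P)} exceeds the exhaustive cap {_MAX_P}")
    C = set(core.core)
    for z in range(len(P) + 1):
        optimal = [
            frozenset(sub)
            for sub in itertools.combinations(P, z)
            if _signed_feasible(
                model, C | set(sub), set(P) - set(sub), eps
            )
        ]
        if optimal:
            return z, optimal
    raise InfeasibleError("core set infeasible: no subset of P activates it")


def brute_force_aos_extrema(
    model: MetabolicModel,
    data: ReactionData,
    solution: RegrExSolution,
    w: np.ndarray | None = None,
    slack: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-reaction flux span over the fitted optimum face.

    Enumerates the direction pattern of every reversible reaction; within a
    pattern |v| is linear, so the face {same weighted data distance, same
    L1 norm} is a polytope and min/max of each coordinate are plain LPs.
    """
    n = model.n_reactions
    rev = np.flatnonzero(model.reversible)
    if rev.size > _MAX_REV_ENUM:
        raise ValidationError("too many reversible reactions for enumeration")
    if w is None:
        w = np.ones(n)
    bounded = data.data_bounded
    nb = bounded.size
    E = solution.weighted_error
    L = solution.l1_norm
    s_E = slack * max(1.0, E)
    s_L = slack * max(1.0, L)

    vmin = np.full(n, np.inf)
    vmax = np.full(n, -np.inf)
    n_var = n + 2 * nb  # v, e+, e-
    for signs in itertools.product((1.0, -1.0), repeat=rev.size):
        sigma = np.ones(n)
        sigma[rev] = signs
        lb = model.lb.copy()
        ub = model.ub.copy()
        lb[rev] = np.where(np.array(signs) > 0, 0.0, model.lb[rev])
        ub[rev] = np.where(np.array(signs) > 0, model.ub[rev], 0.0)
        bounds = [(float(l), float(u)) for l, u in zip(lb, ub)]
        bounds += [(0.0, None)] * (2 * nb)

        A_eq_rows = []
        b_eq = []
        # S v = 0
        for r in range(model.n_metabolites):
            row = np.zeros(n_var)
            row[:n] = model.S[r]
            A_eq_rows.append(row)
            b_eq.append(0.0)
        # e+ - e- = d - sigma v  on R_D
        for k, i in enumerate(bounded):
            row = np.zeros(n_var)
            row[i] = sigma[i]
            row[n + 2 * k] = 1.0
            row[n + 2 * k + 1] = -1.0
            A_eq_rows.append(row)
            b_eq.append(data.value(i))
        A_eq = np.vstack(A_eq_rows) if A_eq_rows else None

        # budget rows: weighted error and L1 norm pinned within slack
        err_row = np.zeros(n_var)
        for k, i in enumerate(bounded):
            err_row[n + 2 * k] = w[i]
            err_row[n + 2 * k + 1] = w[i]
        l1_row = np.zeros(n_var)
        l1_row[:n] = sigma
        A_ub = np.vstack([err_row, -err_row, l1_row, -l1_row])
        b_ub = np.array([E + s_E, -(E - s_E), L + s_L, -(L - s_L)])

        for j in range(n):
            for direction in (1.0, -1.0):
                c = np.zeros(n_var)
                c[j] = direction
                res = linprog(
                    c,
                    A_eq=A_eq,
                    b_eq=np.array(b_eq),
                    A_ub=A_ub,
                    b_ub=b_ub,
                    bounds=bounds,
                    method="highs",
                )
                if res.status != 0:
                    break  # pattern infeasible
                val = direction * res.fun
                if direction > 0:
                    vmin[j] = min(vmin[j], val)
                else:
                    vmax[j] = max(vmax[j], val)
            else:
                continue
            break  # pattern infeasible: skip remaining coordinates
    if not np.all(np.isfinite(vmin)):
        raise InfeasibleError("optimum face empty under every direction pattern")
    return vmin, vmax
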