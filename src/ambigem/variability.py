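"""Flux Variability Analysis, model reduction and flux-cone sampling.

FVA solves, per reaction, ``min/max v_i  s.t.  S v = 0, lb <= v <= ub``
with no further constraints (no fraction-of-optimum locking).  The cone
sampler draws a random point coordinate-wise within the FVA ranges and
projects it onto the cone by minimizing the Euclidean distance, giving an
unconditioned (no-data) baseline against which data-constrained samples
can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .exceptions import InfeasibleError, SolverError
from .model import MetabolicModel


@dataclass
class FluxRange:
    """Per-reaction feasible flux interval over the cone (bounds-only FVA)."""

    reaction_ids: list[str]
    minimum: np.ndarray
    maximum: np.ndarray
    constraint_mode: str = "bounds_only"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": self.reaction_ids, "min": self.minimum, "max": self.maximum}
        )

    def width(self) -> np.ndarray:
        return self.maximum - self.minimum


@dataclass
class FluxSample:
    """A matrix of steady-state flux vectors (rows) in original orientation."""

    matrix: np.ndarray
    reaction_ids: list[str]
    seed: int
    provenance: str  # "cone" | "regrex_aos"
    lam: float | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(reaction_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reaction_ids)


def fva(model: MetabolicModel) -> FluxRange:
    """Reaction-wise min/max flux subject to mass balance and bounds only."""
    n = model.n_reactions
    A = sparse.csr_matrix(model.S)
    b = np.zeros(model.n_metabolites)
    bounds = list(zip(model.lb.tolist(), model.ub.tolist()))
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        for sign, out in ((1.0, vmin), (-1.0, vmax)):
            res = linprog(sign * c, A_eq=A, b_eq=b, bounds=bounds, method="highs")
            if res.status == 2:
                raise InfeasibleError(
                    "model admits no steady-state flux distribution"
                )
            if res.status != 0:
                raise SolverError(f"FVA LP failed on column {j}: {res.message}")
            out[j] = sign * res.fun
    # clamp numerical spill outside the declared bounds
    vmin = np.clip(vmin, model.lb, model.ub)
    vmax = np.clip(vmax, vmin, model.ub)
    return FluxRange(list(model.reaction_ids), vmin, vmax)


def blocked_reactions(
    model: MetabolicModel, tol: float = 1e-6, ranges: FluxRange | None = None
) -> np.ndarray:
    """Indices of reactions whose maximum absolute flux is below ``tol``."""
    rng = ranges or fva(model)
    return np.flatnonzero(
        np.maximum(np.abs(rng.minimum), np.abs(rng.maximum)) < tol
    )


def reduce_model(model: MetabolicModel, blocked_tol: float = 1e-6) -> MetabolicModel:
    """Drop blocked reactions (max |v| < ``blocked_tol`` by FVA) and the
    metabolites they leave orphaned.  Idempotent: the result contains no
    blocked reactions at the same tolerance."""
    blocked = set(blocked_reactions(model, blocked_tol).tolist())
    keep = [j for j in range(model.n_reactions) if j not in blocked]
    if len(keep) == model.n_reactions:
        return model.copy()
    return model.subset(keep)


def cone_sample(
    model: MetabolicModel,
    n: int,
    seed: int = 0,
    ranges: FluxRange | None = None,
    tol: float = 1e-6,
) -> FluxSample:
    """Sample the flux cone by Euclidean projection of uniform draws.

    Each iteration draws ``v_rand`` coordinate-wise uniformly within the
    FVA ranges and solves ``min 0.5 ||v - v_rand||^2`` over the cone.
    """
    rng_state = np.random.default_rng(seed)
    ranges = ranges or fva(model)
    rows = np.empty((n, model.n_reactions))
    for k in range(n):
        v_rand = rng_state.uniform(ranges.minimum, ranges.maximum)
        try:
            rows[k] = _project_onto_cone(model, v_rand, tol)
        except SolverError:
            # one retry with a fresh draw, then give up
            v_rand = rng_state.uniform(ranges.minimum, ranges.maximum)
            rows[k] = _project_onto_cone(model, v_rand, tol)
    return FluxSample(
        matrix=rows,
        reaction_ids=list(model.reaction_ids),
        seed=seed,
        provenance="cone",
    )


def _project_onto_cone(
    model: MetabolicModel, target: np.ndarray, tol: float
) -> np.ndarray:
    n = model.n_reactions
    ident = np.eye(n)

    def fun(v):
        r = v - target
        return 0.5 * float(r @ r)

    def jac(v):
        return v - target

    x0 = np.clip(np.zeros(n), model.lb, model.ub)
    res = minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda v: ident,
        method="trust-constr",
        constraints=[LinearConstraint(model.S, 0.0, 0.0)],
        bounds=Bounds(model.lb, model.ub),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500, "verbose": 0},
    )
    v = np.asarray(res.x)
    residual = float(np.max(np.abs(model.S @ v))) if model.n_metabolites else 0.0
    if residual > tol or np.any(v < model.lb - tol) or np.any(v > model.ub + tol):
        raise SolverError(
            f"cone projection violated constraints (residual {residual:.2e})"
        )
    return np.clip(v, model.lb, model.ub)
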