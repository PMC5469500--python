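"""Thin solver-agnostic layer for LP/MILP construction and solving.

Problems are built symbolically (named variables, two-sided linear
constraints) and handed to SciPy's HiGHS interface (`scipy.optimize.milp`),
which covers both pure LPs and mixed-integer programs.  Variable order is
insertion order, so runs are reproducible: HiGHS is deterministic on a
fixed problem layout with a single thread.

The quadratic flux-cone projection used elsewhere does not go through this
layer (see :mod:`ambigem.variability`).
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .exceptions import SolverError


def _flush_c_stdio() -> None:
    """Flush C-level stdio so buffered solver chatter lands on the fd that
    is active right now, not on whatever fd 1 points to later."""
    try:
        import ctypes

        ctypes.CDLL(None).fflush(None)
    except Exception:
        pass


@contextlib.contextmanager
def _muted_stdout():
    """Silence HiGHS' C-level chatter (fd 1 and 2) during a solve."""
    try:
        saved = [os.dup(fd) for fd in (1, 2)]
    except OSError:
        yield
        return
    _flush_c_stdio()
    try:
        with open(os.devnull, "wb") as null:
            for fd in (1, 2):
                os.dup2(null.fileno(), fd)
        yield
    finally:
        _flush_c_stdio()
        for fd, s in zip((1, 2), saved):
            os.dup2(s, fd)
            os.close(s)


class Status(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    TIME_LIMIT = "time_limit"


@dataclass(frozen=True)
class SolverSpec:
    """Solver parameters.

    ``feasibility_tol`` is the tolerance this package uses for its own
    feasibility checks and equality slacks; ``integrality_tol`` is used when
    rounding binaries out of the solver; ``mip_gap`` is the relative
    optimality gap requested from the MILP solver.
    """

    feasibility_tol: float = 1e-7
    integrality_tol: float = 1e-5
    mip_gap: float = 0.0
    time_limit: float | None = None
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.feasibility_tol <= 0 or self.integrality_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 <= self.mip_gap < 1:
            raise ValueError("mip_gap must be in [0, 1)")


#: Named parameterizations: tight feasibility for the network MILPs,
#: a 1% optimality gap for the alternative-optima sampler.
NETWORK_SPEC = SolverSpec(feasibility_tol=1e-9)
AOS_SPEC = SolverSpec(mip_gap=0.01)


@dataclass
class ProgramResult:
    status: Status
    objective: float | None
    primal: dict[str, float] = field(default_factory=dict)
    gap: float | None = None

    def __getitem__(self, name: str) -> float:
        return self.primal[name]

    def values(self, names) -> np.ndarray:
        return np.array([self.primal[n] for n in names])


class LinearProgram:
    """Symbolic LP/MILP with named variables and two-sided constraints."""

    def __init__(self, name: str = "lp") -> None:
        self.name = name
        self._vars: list[str] = []
        self._pos: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integrality: list[int] = []
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._obj: dict[int, float] = {}
        self._sense = 1.0  # +1 minimize, -1 maximize

    # -- construction -----------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        binary: bool = False,
    ) -> str:
        if name in self._pos:
            raise ValueError(f"duplicate variable {name!r}")
        self._pos[name] = len(self._vars)
        self._vars.append(name)
        if binary:
            lb, ub = max(lb, 0.0), min(ub, 1.0)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integrality.append(1 if binary else 0)
        return name

    def add_constr(
        self,
        coeffs: dict[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        row: dict[int, float] = {}
        for name, c in coeffs.items():
            if c == 0.0:
                continue
            row[self._pos[name]] = row.get(self._pos[name], 0.0) + float(c)
        self._rows.append(row)
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def add_eq(self, coeffs: dict[str, float], rhs: float, slack: float = 0.0) -> None:
        self.add_constr(coeffs, rhs - slack, rhs + slack)

    def set_objective(self, coeffs: dict[str, float], sense: str = "min") -> None:
        self._obj = {self._pos[n]: float(c) for n, c in coeffs.items()}
        self._sense = 1.0 if sense == "min" else -1.0

    @property
    def n_vars(self) -> int:
        return len(self._vars)

    # -- solving ----------------------------------------------------------
    def solve(self, spec: SolverSpec | None = None) -> ProgramResult:
        spec = spec or SolverSpec()
        n = len(self._vars)
        if n == 0:
            raise SolverError("empty program")
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = self._sense * v
        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            for i, row in enumerate(self._rows):
                for j, v in row.items():
                    ri.append(i)
                    ci.append(j)
                    data.append(v)
            A = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self._rows), n)
            )
            constraints = LinearConstraint(
                A, np.array(self._row_lb), np.array(self._row_ub)
            )
        options: dict = {"presolve": True}
        if spec.mip_gap > 0:
            options["mip_rel_gap"] = spec.mip_gap
        if spec.time_limit is not None:
            options["time_limit"] = spec.time_limit
        with _muted_stdout():
            res = milp(
                c=c,
                constraints=constraints,
                integrality=np.array(self._integrality),
                bounds=Bounds(np.array(self._lb), np.array(self._ub)),
                options=options,
            )
        status = {
            0: Status.OPTIMAL,
            1: Status.TIME_LIMIT,
            2: Status.INFEASIBLE,
            3: Status.UNBOUNDED,
        }.get(res.status)
        if status is None:
            raise SolverError(f"{self.name}: solver failure: {res.message}")
        primal: dict[str, float] = {}
        objective = None
        if res.x is not None:
            x = np.asarray(res.x, dtype=float)
            for j, name in enumerate(self._vars):
                v = x[j]
                if self._integrality[j]:
                    r = round(v)
                    if abs(v - r) > spec.integrality_tol:
                        raise SolverError(
                            f"{self.name}: binary {name} not integral ({v})"
                        )
                    v = float(r)
                primal[name] = float(v)
            objective = float(self._sense * res.fun)
        gap = getattr(res, "mip_gap", None)
        return ProgramResult(
            status=status,
            objective=objective,
            primal=primal,
            gap=None if gap is None else float(gap),
        )
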