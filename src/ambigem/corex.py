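"""Parsimonious core-expansion network extraction and its alternative optima.

Given a partition of the reactions into a core set C (must be active in the
context-specific model) and a non-core set P, the extraction MILP selects
the smallest subset of P that lets every core reaction carry at least a
small flux epsilon at steady state; selected non-core reactions are forced
active too and unselected ones are shut off.  A companion MILP then finds,
at the same non-core cardinality Z, the network maximally dissimilar
(by selection mismatches) to a previously found one; iterating it — with a
random 1%-of-non-core state perturbation on stagnation — enumerates an
ensemble of alternative optimal networks.

A four-way confidence classification (core HC plus MC/NC/OT non-core
groups, as produced by CORDA-style tools) is supported by conserving the
cardinality per group instead of globally.  Externally reconstructed
networks (e.g. FastCORE or CORDA output) can be audited by anchoring the
dissimilarity MILP at their inclusion vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InfeasibleError, SolverError, ValidationError
from .model import SplitModel
from .optcore import LinearProgram, NETWORK_SPEC, SolverSpec, Status
from .variability import fva


@dataclass
class CoreSet:
    """Core reactions plus, optionally, a confidence partition of non-core."""

    core: frozenset[int]
    n_reactions: int
    mode: str = "simple"  # "simple" | "corda"
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.core = frozenset(int(i) for i in self.core)
        if any(i < 0 or i >= self.n_reactions for i in self.core):
            raise ValidationError("core indices out of range")
        if self.mode not in {"simple", "corda"}:
            raise ValidationError(f"unknown core mode {self.mode!r}")
        if self.mode == "corda":
            noncore = self.noncore
            groups = {k: frozenset(int(i) for i in v) for k, v in self.groups.items()}
            self.groups = groups
            union: set[int] = set()
            for name, members in groups.items():
                if union & members:
                    raise ValidationError("confidence groups must be disjoint")
                union |= members
            if union != set(noncore):
                raise ValidationError(
                    "confidence groups must partition the non-core set"
                )

    @property
    def noncore(self) -> frozenset[int]:
        return frozenset(range(self.n_reactions)) - self.core

    def group_of(self, i: int) -> str:
        if self.mode != "corda":
            return "P"
        for name, members in self.groups.items():
            if i in members:
                return name
        raise KeyError(i)


@dataclass
class CorExConfig:
    epsilon: float = 1e-4      # minimum active flux
    vmax: float | None = None  # big-M; default = per-column split bound
    z_lb: int | None = None    # optional lower bound on the cardinality

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.vmax is not None and self.vmax <= self.epsilon:
            raise ValidationError("vmax must exceed epsilon")


@dataclass
class ExtractedNetwork:
    """One context-specific network: inclusion vector plus a flux witness."""

    include: np.ndarray        # binary over all reactions, core always 1
    x: dict[int, int]          # selection per non-core reaction index
    Z: int | dict[str, int]    # cardinality (per group in corda mode)
    witness_flux: np.ndarray   # split flux certifying activity at epsilon
    objective_status: str = "optimal"

    def key(self) -> bytes:
        return np.asarray(self.include, dtype=np.uint8).tobytes()


@dataclass
class NetworkEnsemble:
    networks: list[ExtractedNetwork]
    seed: int
    iteration_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.networks)

    def inclusion_matrix(self) -> np.ndarray:
        return np.vstack([n.include for n in self.networks])


# ---------------------------------------------------------------------------


def _build_extraction_system(
    lp: LinearProgram, split: SplitModel, core: CoreSet, cfg: CorExConfig
) -> tuple[list[str], list[str], list[str], dict[int, str]]:
    """Constraints 1-9 of the extraction MILP; returns variable registries."""
    n_irr, n_rev = split.n_irr, split.n_rev
    eps = cfg.epsilon
    v_irr = [
        lp.add_var(f"vI{k}", lb=split.lb_ext[k], ub=split.ub_ext[k])
        for k in range(n_irr)
    ]
    ub_for = split.ub_ext[n_irr : n_irr + n_rev]
    ub_back = split.ub_ext[n_irr + n_rev :]
    v_for = [lp.add_var(f"vF{k}", ub=float(ub_for[k])) for k in range(n_rev)]
    v_back = [lp.add_var(f"vB{k}", ub=float(ub_back[k])) for k in range(n_rev)]

    # 1. mass balance
    S = split.origin.S
    for row in range(split.origin.n_metabolites):
        coeffs: dict[str, float] = {}
        for k in range(n_irr):
            c = S[row, split.irr_idx[k]]
            if c:
                coeffs[v_irr[k]] = c
        for k in range(n_rev):
            c = S[row, split.rev_idx[k]]
            if c:
                coeffs[v_for[k]] = c
                coeffs[v_back[k]] = -c
        if coeffs:
            lp.add_eq(coeffs, 0.0)

    big = cfg.vmax
    x_vars: dict[int, str] = {}
    for k in range(n_irr):
        i = split.irr_idx[k]
        cap = big if big is not None else float(split.ub_ext[k])
        if i in core.core:
            lp.add_constr({v_irr[k]: 1.0}, lb=eps)  # 2
        else:
            xi = lp.add_var(f"x{i}", binary=True)
            x_vars[i] = xi
            lp.add_constr({v_irr[k]: 1.0, xi: -cap}, ub=0.0)  # 4
            lp.add_constr({v_irr[k]: 1.0, xi: -eps}, lb=0.0)  # 5
    for k in range(n_rev):
        i = split.rev_idx[k]
        cap = (
            big
            if big is not None
            else float(max(ub_for[k], ub_back[k]))
        )
        pair = {v_for[k]: 1.0, v_back[k]: 1.0}
        if i in core.core:
            lp.add_constr(pair, lb=eps)  # 3
        else:
            xi = lp.add_var(f"x{i}", binary=True)
            x_vars[i] = xi
            lp.add_constr({**pair, xi: -cap}, ub=0.0)  # 6
            lp.add_constr({**pair, xi: -eps}, lb=0.0)  # 7
        # 8-9: direction exclusivity via y
        y = lp.add_var(f"y{k}", binary=True)
        if ub_for[k] > 0:
            lp.add_constr({v_for[k]: 1.0, y: float(ub_for[k])}, ub=float(ub_for[k]))
        if ub_back[k] > 0:
            lp.add_constr({v_back[k]: 1.0, y: -float(ub_back[k])}, ub=0.0)
    return v_irr, v_for, v_back, x_vars


def _network_from_result(
    split: SplitModel,
    core: CoreSet,
    x_vars: dict[int, str],
    v_names: list[str],
    res,
) -> ExtractedNetwork:
    n = split.origin.n_reactions
    include = np.zeros(n, dtype=int)
    include[list(core.core)] = 1
    x: dict[int, int] = {}
    for i, name in x_vars.items():
        x[i] = int(round(res[name]))
        include[i] = x[i]
    witness = res.values(v_names)
    if core.mode == "corda":
        Z: int | dict[str, int] = {
            g: int(sum(x[i] for i in members))
            for g, members in core.groups.items()
        }
    else:
        Z = int(sum(x.values()))
    return ExtractedNetwork(include=include, x=x, Z=Z, witness_flux=witness)


def corex(
    split: SplitModel,
    core: CoreSet,
    cfg: CorExConfig | None = None,
    spec: SolverSpec | None = None,
) -> ExtractedNetwork:
    """Extract the minimum-cardinality consistent context-specific network."""
    cfg = cfg or CorExConfig()
    spec = spec or NETWORK_SPEC
    lp = LinearProgram("corex")
    v_irr, v_for, v_back, x_vars = _build_extraction_system(lp, split, core, cfg)
    if cfg.z_lb is not None and x_vars:
        lp.add_constr({xi: 1.0 for xi in x_vars.values()}, lb=float(cfg.z_lb))
    if x_vars:
        lp.set_objective({xi: 1.0 for xi in x_vars.values()}, "min")
    else:
        lp.set_objective({v_irr[0] if v_irr else v_for[0]: 0.0}, "min")
    res = lp.solve(spec)
    if res.status == Status.INFEASIBLE:
        raise InfeasibleError(_core_diagnosis(split, core, cfg))
    if res.status != Status.OPTIMAL:
        raise SolverError(f"extraction ended with status {res.status}")
    return _network_from_result(split, core, x_vars, v_irr + v_for + v_back, res)


def _core_diagnosis(split: SplitModel, core: CoreSet, cfg: CorExConfig) -> str:
    model = split.origin
    try:
        ranges = fva(model)
        widths = np.maximum(np.abs(ranges.minimum), np.abs(ranges.maximum))
        dead = [
            model.reaction_ids[i]
            for i in sorted(core.core)
            if widths[i] < cfg.epsilon
        ]
    except Exception:
        dead = []
    hint = f"; FVA-blocked core reactions: {dead}" if dead else ""
    return f"core set cannot be made consistent at epsilon={cfg.epsilon}{hint}"


def altnet_step(
    split: SplitModel,
    core: CoreSet,
    x_opt: dict[int, int],
    Z: int | dict[str, int],
    cfg: CorExConfig | None = None,
    spec: SolverSpec | None = None,
    tie_break_rng: np.random.Generator | None = None,
) -> tuple[ExtractedNetwork, int]:
    """Find the network maximally dissimilar to ``x_opt`` at cardinality Z.

    Returns ``(network, mismatch_count)``; a mismatch count of zero signals
    that the anchor is the unique optimum at this cardinality.

    Many networks may tie at the maximal mismatch count; ``tie_break_rng``
    adds a seeded perturbation below 1e-4 to each mismatch coefficient,
    which provably cannot change the attained mismatch count but varies
    which maximizer the solver returns, diversifying iterated searches.
    """
    cfg = cfg or CorExConfig()
    spec = spec or NETWORK_SPEC
    lp = LinearProgram("altnet")
    v_irr, v_for, v_back, x_vars = _build_extraction_system(lp, split, core, cfg)
    noncore = sorted(x_vars)
    if set(x_opt) != set(noncore):
        raise ValidationError("x_opt must cover exactly the non-core set")

    # 10. cardinality conservation (per confidence group in corda mode)
    if core.mode == "corda":
        if not isinstance(Z, dict):
            raise ValidationError("corda mode needs per-group cardinalities")
        for g, members in core.groups.items():
            mem = [i for i in members if i in x_vars]
            lp.add_eq({x_vars[i]: 1.0 for i in mem}, float(Z[g]))
    else:
        lp.add_eq({x_vars[i]: 1.0 for i in noncore}, float(int(Z)))

    # 11-12. binary mismatch variables, mutually exclusive
    obj: dict[str, float] = {}
    jitter = (
        tie_break_rng.uniform(0.0, 1e-4, size=len(noncore))
        if tie_break_rng is not None
        else np.zeros(len(noncore))
    )
    for pos, i in enumerate(noncore):
        dp = lp.add_var(f"dp{i}", binary=True)
        dm = lp.add_var(f"dm{i}", binary=True)
        lp.add_eq({x_vars[i]: 1.0, dp: 1.0, dm: -1.0}, float(x_opt[i]))
        lp.add_constr({dp: 1.0, dm: 1.0}, ub=1.0)
        obj[dp] = 1.0 + jitter[pos]
        obj[dm] = 1.0 + jitter[pos]
    lp.set_objective(obj, "max")
    res = lp.solve(spec)
    if res.status == Status.INFEASIBLE:
        raise InfeasibleError(
            "dissimilarity step infeasible: the anchor is not feasible "
            "at the stated cardinality"
        )
    if res.status != Status.OPTIMAL:
        raise SolverError(f"dissimilarity step ended with status {res.status}")
    net = _network_from_result(split, core, x_vars, v_irr + v_for + v_back, res)
    mismatches = sum(int(net.x[i] != x_opt[i]) for i in noncore)
    return net, mismatches


def altnet_enumerate(
    split: SplitModel,
    core: CoreSet,
    x_seed: ExtractedNetwork,
    cfg: CorExConfig | None = None,
    spec: SolverSpec | None = None,
    max_iter: int = 50,
    seed: int = 0,
) -> NetworkEnsemble:
    """Iteratively enumerate alternative optimal networks.

    Each newly found network is fed back as the next anchor.  On stagnation
    (duplicate or zero-mismatch result) the state of ``ceil(0.01 |P|)``
    uniformly chosen non-core entries of the last anchor is flipped and the
    search continues; perturbed vectors serve only as anchors and are never
    stored.  Terminates after ``max_iter`` total steps or ``max_iter``
    stagnations, returning distinct feasible networks only.
    """
    cfg = cfg or CorExConfig()
    spec = spec or NETWORK_SPEC
    rng = np.random.default_rng(seed)
    noncore = sorted(x_seed.x)
    n_flip = max(1, int(np.ceil(0.01 * len(noncore))))
    ensemble = [x_seed]
    seen = {x_seed.key()}
    log: list[str] = []
    anchor = dict(x_seed.x)
    stagnations = 0
    for step in range(max_iter):
        net, mismatches = altnet_step(
            split, core, anchor, x_seed.Z, cfg, spec, tie_break_rng=rng
        )
        if mismatches > 0 and net.key() not in seen:
            ensemble.append(net)
            seen.add(net.key())
            anchor = dict(net.x)
            log.append(f"step {step}: new network ({mismatches} mismatches)")
            continue
        stagnations += 1
        log.append(
            f"step {step}: stagnation ({mismatches} mismatches); perturbing"
        )
        if stagnations >= max_iter:
            break
        flip = rng.choice(noncore, size=min(n_flip, len(noncore)), replace=False)
        anchor = dict(ensemble[-1].x)
        for i in flip:
            anchor[int(i)] = 1 - anchor[int(i)]
    return NetworkEnsemble(networks=ensemble, seed=seed, iteration_log=log)


def audit_external_network(
    split: SplitModel,
    core: CoreSet,
    include: np.ndarray,
    cfg: CorExConfig | None = None,
    spec: SolverSpec | None = None,
) -> ExtractedNetwork:
    """Turn an externally reconstructed network into an enumeration anchor.

    Verifies that the inclusion vector covers the core and that the network
    is consistent at epsilon (every included reaction active, every
    excluded non-core reaction shut off), then returns it as an
    :class:`ExtractedNetwork` whose cardinality anchors the dissimilarity
    search.
    """
    cfg = cfg or CorExConfig()
    spec = spec or NETWORK_SPEC
    include = np.asarray(include, dtype=int)
    if include.shape != (split.origin.n_reactions,):
        raise ValidationError("inclusion vector has wrong length")
    missing = [i for i in sorted(core.core) if include[i] != 1]
    if missing:
        ids = [split.origin.reaction_ids[i] for i in missing]
        raise ValidationError(f"inclusion vector misses core reactions: {ids}")

    lp = LinearProgram("audit")
    v_irr, v_for, v_back, x_vars = _build_extraction_system(lp, split, core, cfg)
    for i, xi in x_vars.items():
        lp.add_eq({xi: 1.0}, float(include[i]))
    lp.set_objective({next(iter(x_vars.values()), (v_irr + v_for + v_back)[0]): 0.0})
    res = lp.solve(spec)
    if res.status != Status.OPTIMAL:
        raise InfeasibleError(_audit_diagnosis(split, core, include, cfg))
    return _network_from_result(split, core, x_vars, v_irr + v_for + v_back, res)


def _audit_diagnosis(split, core, include, cfg) -> str:
    model = split.origin
    sub_idx = np.flatnonzero(include == 1)
    sub = model.subset(sub_idx)
    try:
        ranges = fva(sub)
        widths = np.maximum(np.abs(ranges.minimum), np.abs(ranges.maximum))
        dead = [
            sub.reaction_ids[k]
            for k in range(sub.n_reactions)
            if widths[k] < cfg.epsilon
        ]
    except Exception:
        dead = []
    hint = f"; included reactions inactive at epsilon: {dead}" if dead else ""
    return f"external network infeasible at epsilon={cfg.epsilon}{hint}"
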