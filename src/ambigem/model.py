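"""Core in-memory containers for constraint-based metabolic models.

A genome-scale metabolic model (GEM) is held as a dense stoichiometric
matrix ``S`` (metabolites x reactions) together with per-reaction flux
bounds, gene-protein-reaction (GPR) rules and pathway (subsystem) labels.
Steady-state flux vectors live in the flux cone
``F = {v : S v = 0, lb <= v <= ub}``.

Reversibility is defined by the bounds: a reaction is reversible iff its
lower bound is negative, i.e. the bounds define the feasible cone and win
over any external reversibility flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError

#: Conventional numeric stand-in for an unbounded flux (COBRA default).
DEFAULT_BOUND = 1000.0


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, GPR rules and subsystem labels.

    Attributes
    ----------
    reaction_ids, metabolite_ids
        Unique identifiers; column/row order of ``S`` follows these lists.
    S
        Dense ``(n_metabolites, n_reactions)`` array of stoichiometric
        coefficients.
    lb, ub
        Per-reaction flux bounds (arbitrary flux units, e.g. mmol/gDW/h).
    gpr
        Per-reaction boolean expression over gene ids ("" if none).
    subsystem
        Per-reaction pathway label ("" if unassigned).
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: list[str] = field(default_factory=list)
    subsystem: list[str] = field(default_factory=list)
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n = len(self.reaction_ids)
        if not self.gpr:
            self.gpr = [""] * n
        if not self.subsystem:
            self.subsystem = [""] * n
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.reaction_ids), len(self.metabolite_ids)
        if self.S.shape != (m, n):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for name, arr in (("lb", self.lb), ("ub", self.ub)):
            if arr.shape != (n,):
                raise ValidationError(f"{name} has length {arr.shape}, expected {n}")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise ValidationError("gpr/subsystem length mismatch")
        if len(set(self.reaction_ids)) != n:
            raise ValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != m:
            raise ValidationError("duplicate metabolite ids")
        bad = np.flatnonzero(self.lb > self.ub)
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ValidationError(f"lb > ub for reaction {rid!r}")

    # -- derived views ----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Boolean mask: reversible iff lb < 0."""
        return self.lb < 0

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def exchange_mask(self) -> np.ndarray:
        """Reactions touching at most one metabolite (boundary reactions)."""
        return (self.S != 0).sum(axis=0) <= 1

    def subset(self, keep: Sequence[int] | np.ndarray) -> "MetabolicModel":
        """Submodel with the given reaction columns; drops orphan metabolites."""
        keep = np.asarray(keep, dtype=int)
        S = self.S[:, keep]
        used = np.flatnonzero((S != 0).any(axis=1))
        return MetabolicModel(
            reaction_ids=[self.reaction_ids[j] for j in keep],
            metabolite_ids=[self.metabolite_ids[i] for i in used],
            S=S[used, :],
            lb=self.lb[keep],
            ub=self.ub[keep],
            gpr=[self.gpr[j] for j in keep],
            subsystem=[self.subsystem[j] for j in keep],
            model_id=self.model_id,
        )

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
        )


@dataclass
class ReactionData:
    """Expression-derived reaction scores ``d`` over the data-bounded set.

    ``d`` holds one non-negative value per reaction; NaN marks data-orphan
    reactions (no GPR, or GPR over unmeasured genes only).
    """

    d: np.ndarray
    reaction_ids: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.reaction_ids),):
            raise ValidationError("d length must match reaction_ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.d < 0):
                raise ValidationError("reaction data values must be >= 0")

    @property
    def data_bounded(self) -> np.ndarray:
        """Indices of reactions with an associated data value (R_D)."""
        return np.flatnonzero(~np.isnan(self.d))

    @property
    def data_orphan(self) -> np.ndarray:
        """Indices of reactions without data (complement of R_D)."""
        return np.flatnonzero(np.isnan(self.d))

    def value(self, i: int) -> float:
        return float(self.d[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "d": self.d,
                "is_data_bounded": ~np.isnan(self.d),
            }
        )


@dataclass
class SplitModel:
    """Irreversible reformulation of a model: reversible columns duplicated.

    Column order is irreversible | forward | backward.  Forward columns keep
    the original stoichiometry with bounds [0, ub]; backward columns are the
    negated stoichiometry with bounds [0, -lb]; all split fluxes are
    non-negative.  ``irr_idx``/``rev_idx`` map split blocks back to original
    reaction indices.
    """

    origin: MetabolicModel
    S_ext: np.ndarray
    lb_ext: np.ndarray
    ub_ext: np.ndarray
    irr_idx: np.ndarray
    rev_idx: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.S_ext.shape[1]

    @property
    def n_irr(self) -> int:
        return self.irr_idx.size

    @property
    def n_rev(self) -> int:
        return self.rev_idx.size

    def col_irr(self, k: int) -> int:
        """Split column of the k-th irreversible reaction."""
        return k

    def col_for(self, k: int) -> int:
        """Split column of the forward direction of the k-th reversible."""
        return self.n_irr + k

    def col_back(self, k: int) -> int:
        """Split column of the backward direction of the k-th reversible."""
        return self.n_irr + self.n_rev + k

    def recombine(self, v_ext: np.ndarray) -> np.ndarray:
        """Map a split flux vector back to the original orientation."""
        v_ext = np.asarray(v_ext, dtype=float)
        v = np.zeros(self.origin.n_reactions)
        v[self.irr_idx] = v_ext[: self.n_irr]
        fwd = v_ext[self.n_irr : self.n_irr + self.n_rev]
        back = v_ext[self.n_irr + self.n_rev :]
        v[self.rev_idx] = fwd - back
        return v


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Split reversible reactions into non-negative forward/backward columns."""
    rev = model.reversible
    irr_idx = np.flatnonzero(~rev)
    rev_idx = np.flatnonzero(rev)
    S_irr = model.S[:, irr_idx]
    S_for = model.S[:, rev_idx]
    S_back = -model.S[:, rev_idx]
    S_ext = np.hstack([S_irr, S_for, S_back])
    lb_ext = np.concatenate(
        [model.lb[irr_idx], np.zeros(rev_idx.size), np.zeros(rev_idx.size)]
    )
    ub_ext = np.concatenate(
        [model.ub[irr_idx], model.ub[rev_idx], -model.lb[rev_idx]]
    )
    # reversible reactions with ub < 0 would get a negative forward cap
    ub_ext = np.maximum(ub_ext, 0.0)
    return SplitModel(
        origin=model,
        S_ext=S_ext,
        lb_ext=lb_ext,
        ub_ext=ub_ext,
        irr_idx=irr_idx,
        rev_idx=rev_idx,
    )


def make_bounds_finite(
    lb: Iterable[float], ub: Iterable[float], bound: float = DEFAULT_BOUND
) -> tuple[np.ndarray, np.ndarray]:
    """Replace infinite bounds by +-``bound`` (needed as big-M constants)."""
    lb = np.asarray(list(lb), dtype=float)
    ub = np.asarray(list(ub), dtype=float)
    lb[np.isneginf(lb)] = -bound
    ub[np.isposinf(ub)] = bound
    return lb, ub
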