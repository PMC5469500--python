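"""Mapping gene expression onto reactions through GPR rules.

The default evaluation semantics follow the standard enzyme-complex /
isoenzyme interpretation: AND takes the minimum over the complex subunits,
OR the maximum over isoenzymes.  Both operators are configurable.

Per replicate, gene values are scaled to the replicate maximum before GPR
evaluation; replicate means are taken as the representative reaction value.
Reactions whose GPR is empty, or references only unmeasured genes, become
data-orphan.  Genes missing from a partially measured rule are dropped from
the expression tree before evaluation.
"""

from __future__ import annotations

import ast
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MappingError, ValidationError
from .model import MetabolicModel, ReactionData

Aggregate = Callable[[Sequence[float]], float]


def gpr_genes(rule: str) -> frozenset[str]:
    """Gene ids referenced by a GPR rule string."""
    tree = _parse(rule)
    if tree is None:
        return frozenset()
    return frozenset(
        node.id for node in ast.walk(tree) if isinstance(node, ast.Name)
    )


def eval_gpr(
    rule: str,
    values: Mapping[str, float],
    and_op: Aggregate = min,
    or_op: Aggregate = max,
) -> float | None:
    """Evaluate a GPR rule against gene values.

    Returns ``None`` when the rule is empty or no referenced gene is
    measured.  Unmeasured genes are ignored inside partially measured
    AND/OR groups.
    """
    tree = _parse(rule)
    if tree is None:
        return None
    return _eval_node(tree, values, and_op, or_op)


def _parse(rule: str) -> ast.expr | None:
    rule = (rule or "").strip()
    if not rule:
        return None
    normalized = rule.replace(" AND ", " and ").replace(" OR ", " or ")
    try:
        return ast.parse(normalized, mode="eval").body
    except SyntaxError as exc:
        raise ValidationError(f"cannot parse GPR rule {rule!r}: {exc}") from exc


def _eval_node(node, values, and_op, or_op) -> float | None:
    if isinstance(node, ast.Name):
        v = values.get(node.id)
        return None if v is None else float(v)
    if isinstance(node, ast.BoolOp):
        agg = and_op if isinstance(node.op, ast.And) else or_op
        parts = [_eval_node(c, values, and_op, or_op) for c in node.values]
        parts = [p for p in parts if p is not None]
        return agg(parts) if parts else None
    raise ValidationError(f"unsupported GPR syntax node {type(node).__name__}")


def map_expression_to_reactions(
    model: MetabolicModel,
    replicates: Sequence[Mapping[str, float]] | Mapping[str, float] | pd.Series,
    and_op: Aggregate = min,
    or_op: Aggregate = max,
) -> ReactionData:
    """Scale, GPR-map and replicate-average expression data.

    Parameters
    ----------
    replicates
        One gene->value table or a sequence of them (biological replicates).
        Values must be non-negative, one value per gene id.
    """
    if isinstance(replicates, (Mapping, pd.Series)):
        replicates = [replicates]
    if not replicates:
        raise MappingError("no expression replicates given")

    model_genes: set[str] = set()
    rule_genes = [gpr_genes(r) for r in model.gpr]
    for g in rule_genes:
        model_genes |= g

    per_rep: list[np.ndarray] = []
    for rep in replicates:
        series = pd.Series(rep, dtype=float)
        if series.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression table")
        if (series < 0).any():
            raise ValidationError("expression values must be >= 0")
        if not model_genes & set(series.index):
            raise MappingError(
                "no overlap between expression gene ids and model GPR genes"
            )
        peak = series.max()
        scaled = (series / peak if peak > 0 else series).to_dict()
        vals = np.full(model.n_reactions, np.nan)
        for j, rule in enumerate(model.gpr):
            v = eval_gpr(rule, scaled, and_op, or_op)
            if v is not None:
                vals[j] = v
        per_rep.append(vals)

    stacked = np.vstack(per_rep)
    all_nan = np.isnan(stacked).all(axis=0)
    d = np.full(stacked.shape[1], np.nan)
    if (~all_nan).any():
        d[~all_nan] = np.nanmean(stacked[:, ~all_nan], axis=0)
    return ReactionData(d=d, reaction_ids=list(model.reaction_ids))
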