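"""Model and table I/O.

Two model formats are supported: SBML Level 3 + FBC (read through cobrapy)
and a plain JSON dialect that round-trips every field of
:class:`~ambigem.model.MetabolicModel` bit-for-bit.  Expression tables are
two-column CSV/TSV files (gene_id, value).

JSON dialect::

    {
      "id": "toy",
      "metabolites": ["A", "B"],
      "reactions": [
        {"id": "R1", "lb": 0.0, "ub": 10.0, "gpr": "g1 and g2",
         "subsystem": "demo"}
      ],
      "S": [["A", "R1", 1.0], ...]          # (metabolite, reaction, coeff)
    }
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .model import DEFAULT_BOUND, MetabolicModel, ReactionData, make_bounds_finite


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML-FBC or the JSON dialect.

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the suffix when
    omitted (``.xml``/``.sbml`` -> sbml, ``.json`` -> json).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        met_ids = list(doc["metabolites"])
        rxns = doc["reactions"]
        triplets = doc["S"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing required key {exc}") from exc
    rxn_ids = [r["id"] for r in rxns]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_pos = {r: j for j, r in enumerate(rxn_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for met, rxn, coef in triplets:
        if met not in met_pos:
            raise FormatError(f"{path}: S references unknown metabolite {met!r}")
        if rxn not in rxn_pos:
            raise FormatError(f"{path}: S references unknown reaction {rxn!r}")
        S[met_pos[met], rxn_pos[rxn]] = float(coef)
    lb = [float(r["lb"]) for r in rxns]
    ub = [float(r["ub"]) for r in rxns]
    lb, ub = make_bounds_finite(lb, ub)
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=[r.get("gpr", "") for r in rxns],
        subsystem=[r.get("subsystem", "") for r in rxns],
        model_id=doc.get("id", "model"),
    )


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model; bounds win over the SBML reversible flag."""
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            S[met_pos[met.id], j] = float(coef)
    lb, ub = make_bounds_finite(
        (r.lower_bound for r in cm.reactions),
        (r.upper_bound for r in cm.reactions),
    )
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=[r.gene_reaction_rule or "" for r in cm.reactions],
        subsystem=[r.subsystem or "" for r in cm.reactions],
        model_id=cm.id or "model",
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the JSON dialect (lossless round-trip)."""
    rows, cols = np.nonzero(model.S)
    doc = {
        "id": model.model_id,
        "metabolites": list(model.metabolite_ids),
        "reactions": [
            {
                "id": rid,
                "lb": float(model.lb[j]),
                "ub": float(model.ub[j]),
                "gpr": model.gpr[j],
                "subsystem": model.subsystem[j],
            }
            for j, rid in enumerate(model.reaction_ids)
        ],
        "S": [
            [model.metabolite_ids[i], model.reaction_ids[j], float(model.S[i, j])]
            for i, j in zip(rows.tolist(), cols.tolist())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_expression(path: str | Path) -> pd.Series:
    """Read a two-column gene_id,value table (CSV or TSV by suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns gene_id,value")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").values,
        index=df.iloc[:, 0].astype(str).values,
    )
    if s.isna().any():
        raise FormatError(f"{path}: non-numeric expression values")
    if (s < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return s


def write_reaction_data(data: ReactionData, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_reaction_data(path: str | Path, model) -> ReactionData:
    """Read a reaction_id,d table; reactions absent from the table are
    data-orphan."""
    df = pd.read_csv(path)
    if not {"reaction_id", "d"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns reaction_id,d")
    d = np.full(model.n_reactions, np.nan)
    for rid, val in zip(df["reaction_id"], df["d"]):
        d[model.index(str(rid))] = float(val)
    return ReactionData(d=d, reaction_ids=list(model.reaction_ids))


def read_core_set(path: str | Path, model):
    """Read a core / confidence classification CSV (reaction_id, group).

    Group labels ``core``/``C``/``HC`` mark core reactions.  If any of
    ``MC``/``NC``/``OT`` appear, the file is read as a four-way confidence
    classification and unlisted reactions default to OT.
    """
    from .corex import CoreSet

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns reaction_id,group")
    rid_col, grp_col = df.columns[:2]
    groups: dict[str, set[int]] = {}
    for rid, grp in zip(df[rid_col], df[grp_col]):
        groups.setdefault(str(grp).upper(), set()).add(model.index(str(rid)))
    core = set()
    for label in ("CORE", "C", "HC"):
        core |= groups.pop(label, set())
    corda_labels = {"MC", "NC", "OT"} & set(groups)
    if corda_labels:
        noncore = set(range(model.n_reactions)) - core
        listed = set().union(*groups.values()) if groups else set()
        parts = {k: frozenset(groups.get(k, set())) for k in ("MC", "NC", "OT")}
        parts["OT"] = frozenset(parts["OT"] | (noncore - listed))
        return CoreSet(
            core=frozenset(core),
            n_reactions=model.n_reactions,
            mode="corda",
            groups=parts,
        )
    return CoreSet(core=frozenset(core), n_reactions=model.n_reactions)
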