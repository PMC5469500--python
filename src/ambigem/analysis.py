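"""Downstream statistics over network ensembles and flux samples.

Covers binarization of flux vectors at an activity threshold, pairwise
Hamming distances between inclusion vectors, the active/variable/inactive
classification of non-core reactions, pathway (subsystem) ambiguity
scores, the one-sided rank-sum comparison of two distance distributions,
and a metabolic-task feasibility harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse, stats
from scipy.optimize import linprog

from .corex import NetworkEnsemble
from .exceptions import ValidationError
from .model import MetabolicModel
from .variability import FluxSample

ACTIVITY_THRESHOLD = 1e-6


def binarize(
    values: FluxSample | np.ndarray,
    threshold: float = ACTIVITY_THRESHOLD,
    dedup: bool = False,
) -> np.ndarray:
    """1 where |v| >= threshold, 0 otherwise; optionally drop repeated rows."""
    matrix = values.matrix if isinstance(values, FluxSample) else np.asarray(values)
    single = matrix.ndim == 1
    matrix = np.atleast_2d(matrix)
    binary = (np.abs(matrix) >= threshold).astype(int)
    if dedup:
        binary = np.unique(binary, axis=0)
    return binary[0] if single and not dedup else binary


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("Hamming distance needs equal-length vectors")
    return int(np.sum(np.abs(a - b)))


@dataclass
class DistanceReport:
    """Summary of the pairwise Hamming distances across an ensemble."""

    distances: np.ndarray        # condensed upper-triangle vector
    n_networks: int
    n_noncore: int
    n_reactions: int

    @property
    def max(self) -> int:
        return int(self.distances.max()) if self.distances.size else 0

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if self.distances.size else 0.0

    @property
    def cv(self) -> float:
        if self.distances.size == 0 or self.mean == 0:
            return 0.0
        return float(self.distances.std() / self.mean)

    @property
    def max_pct_noncore(self) -> float:
        return 100.0 * self.max / self.n_noncore if self.n_noncore else 0.0

    def summary(self) -> dict:
        return {
            "P": self.n_noncore,
            "n_models": self.n_networks,
            "MR_max": self.max,
            "MR_max_pct_noncore": self.max_pct_noncore,
            "MR_mean": self.mean,
            "MR_cv": self.cv,
            "MR_mean_norm_total": self.mean / self.n_reactions
            if self.n_reactions
            else 0.0,
        }


def hamming_matrix(binary: np.ndarray, n_noncore: int | None = None) -> DistanceReport:
    """Pairwise mismatch counts over rows of a binary inclusion matrix."""
    binary = np.asarray(binary)
    n, width = binary.shape
    dists = []
    for i in range(n):
        diff = np.abs(binary[i + 1 :] - binary[i]).sum(axis=1)
        dists.extend(diff.tolist())
    return DistanceReport(
        distances=np.array(dists, dtype=float),
        n_networks=n,
        n_noncore=n_noncore if n_noncore is not None else width,
        n_reactions=width,
    )


def ranksum_compare(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided rank-sum p-value for H1: distances in ``a`` < those in ``b``."""
    return float(stats.mannwhitneyu(a, b, alternative="less").pvalue)


@dataclass
class NonCoreClassification:
    noncore: list[int]
    frequency: pd.Series        # inclusion fraction per non-core reaction
    active_set: frozenset[int]
    variable_set: frozenset[int]
    inactive_set: frozenset[int]

    def ranked(self, model: MetabolicModel | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"reaction_index": self.noncore, "frequency": self.frequency.values}
        )
        if model is not None:
            df["reaction_id"] = [model.reaction_ids[i] for i in self.noncore]
            df["subsystem"] = [model.subsystem[i] for i in self.noncore]
        return df.sort_values("frequency", ascending=False, kind="stable")


def classify_noncore(ensemble: NetworkEnsemble) -> NonCoreClassification:
    """Three-way partition of non-core reactions by ensemble frequency."""
    if not ensemble.networks:
        raise ValidationError("empty ensemble")
    noncore = sorted(ensemble.networks[0].x)
    counts = np.zeros(len(noncore))
    for net in ensemble.networks:
        counts += np.array([net.x[i] for i in noncore], dtype=float)
    freq = counts / len(ensemble.networks)
    active = frozenset(i for i, f in zip(noncore, freq) if f == 1.0)
    inactive = frozenset(i for i, f in zip(noncore, freq) if f == 0.0)
    variable = frozenset(noncore) - active - inactive
    return NonCoreClassification(
        noncore=noncore,
        frequency=pd.Series(freq, index=noncore),
        active_set=active,
        variable_set=variable,
        inactive_set=inactive,
    )


@dataclass
class PathwayScoreTable:
    table: pd.DataFrame
    normalization: str


def pathway_scores(
    classification: NonCoreClassification,
    model: MetabolicModel,
    normalization: str = "total_noncore",
) -> PathwayScoreTable:
    """Per-subsystem representation of the active/variable/inactive sets.

    ``total_noncore`` divides each group count by the size of the whole
    non-core set; ``per_pathway`` divides by the pathway's own non-core
    size (so a pathway entirely in one class scores 1).
    """
    if normalization not in {"total_noncore", "per_pathway"}:
        raise ValidationError(f"unknown normalization {normalization!r}")
    total_p = len(classification.noncore)
    rows = []
    labels = [model.subsystem[i] or "unassigned" for i in classification.noncore]
    for pathway in sorted(set(labels)):
        members = [
            i
            for i, lab in zip(classification.noncore, labels)
            if lab == pathway
        ]
        a = sum(1 for i in members if i in classification.active_set)
        v = sum(1 for i in members if i in classification.variable_set)
        ina = sum(1 for i in members if i in classification.inactive_set)
        denom = total_p if normalization == "total_noncore" else max(len(members), 1)
        rows.append(
            {
                "pathway": pathway,
                "A_M": a,
                "V_M": v,
                "I_M": ina,
                "S_A": a / denom if denom else 0.0,
                "S_V": v / denom if denom else 0.0,
                "S_I": ina / denom if denom else 0.0,
            }
        )
    return PathwayScoreTable(pd.DataFrame(rows), normalization)


# -- metabolic tasks --------------------------------------------------------


@dataclass
class MetabolicTask:
    task_id: str
    uptakes: dict[str, tuple[float, float]]  # exchange id -> (lb, ub)
    product: str                             # exchange id to maximize
    min_flux: float = ACTIVITY_THRESHOLD


@dataclass
class TaskSuite:
    tasks: list[MetabolicTask]
    pass_threshold: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "TaskSuite":
        doc = yaml.safe_load(Path(path).read_text())
        tasks = [
            MetabolicTask(
                task_id=str(t["id"]),
                uptakes={
                    k: (float(v[0]), float(v[1])) for k, v in t["uptakes"].items()
                },
                product=t["product"],
                min_flux=float(t.get("min_flux", ACTIVITY_THRESHOLD)),
            )
            for t in doc.get("tasks", [])
        ]
        return cls(tasks=tasks, pass_threshold=float(doc.get("pass_threshold", 1.0)))

    def validate(self, model: MetabolicModel) -> None:
        known = set(model.reaction_ids)
        for t in self.tasks:
            refs = set(t.uptakes) | {t.product}
            missing = refs - known
            if missing:
                raise ValidationError(
                    f"task {t.task_id!r} references unknown exchanges: "
                    f"{sorted(missing)}"
                )


@dataclass
class TaskResults:
    results: pd.DataFrame  # columns: task_id, passed, achieved_flux
    fraction_passed: float

    def all_passed(self) -> bool:
        return bool(self.results["passed"].all())


def run_tasks(
    model: MetabolicModel,
    suite: TaskSuite,
    tol: float = 1e-9,
) -> TaskResults:
    """Evaluate each task by LP: close every exchange uptake, open the
    task's uptakes at the stated bounds, and check whether the product
    exchange can reach its required minimum flux (secretion through other
    exchanges stays open)."""
    suite.validate(model)
    if not suite.tasks:
        warnings.warn("empty task suite: fraction reported as 1")
        return TaskResults(
            pd.DataFrame(columns=["task_id", "passed", "achieved_flux"]), 1.0
        )
    exch = model.exchange_mask()
    A = sparse.csr_matrix(model.S)
    b = np.zeros(model.n_metabolites)
    records = []
    for task in suite.tasks:
        lb = model.lb.copy()
        ub = model.ub.copy()
        lb[exch] = np.maximum(lb[exch], 0.0)  # no uptake except as granted
        for rid, (tlo, thi) in task.uptakes.items():
            j = model.index(rid)
            lb[j], ub[j] = tlo, thi
        j_prod = model.index(task.product)
        c = np.zeros(model.n_reactions)
        c[j_prod] = -1.0  # maximize product export
        res = linprog(
            c, A_eq=A, b_eq=b, bounds=list(zip(lb, ub)), method="highs"
        )
        achieved = -res.fun if res.status == 0 else 0.0
        passed = res.status == 0 and achieved >= task.min_flux - tol
        records.append(
            {
                "task_id": task.task_id,
                "passed": bool(passed),
                "achieved_flux": float(achieved),
            }
        )
    df = pd.DataFrame(records)
    return TaskResults(df, float(df["passed"].mean()))


def filter_ensemble_by_tasks(
    ensemble: NetworkEnsemble,
    model: MetabolicModel,
    suite: TaskSuite,
) -> NetworkEnsemble:
    """Keep only networks whose induced submodel passes every task."""
    kept = []
    for net in ensemble.networks:
        sub = model.subset(np.flatnonzero(net.include == 1))
        try:
            res = run_tasks(sub, suite)
        except ValidationError:
            continue  # a referenced exchange was excluded: the task fails
        if res.all_passed():
            kept.append(net)
    return NetworkEnsemble(
        networks=kept,
        seed=ensemble.seed,
        iteration_log=ensemble.iteration_log + ["task filter applied"],
    )
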