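"""Shannon-entropy summaries of sampled flux distributions.

Per reaction, sampled flux values are binned into ``n_bins`` equal-width
intervals spanning the reaction's sampled range and the entropy
``H_i = -sum_k f_ik ln f_ik`` (natural log, nats) of the bin frequencies is
reported; a constant column has H = 0 by convention, the maximum is
``ln(n_bins)``.  Group sums over the data-bounded and data-orphan
partition, the total and the mean quantify the overall ambiguity of a
data-integration problem.  The fixed-direction fraction reports how many
reversible reactions that carry flux anywhere in the sample keep a single
sign across it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import MetabolicModel, ReactionData
from .variability import FluxRange, FluxSample


@dataclass
class EntropyReport:
    reaction_ids: list[str]
    H: np.ndarray
    n_bins: int
    H_Data: float | None = None
    H_Orphan: float | None = None

    @property
    def H_Total(self) -> float:
        return float(self.H.sum())

    @property
    def H_mean(self) -> float:
        return float(self.H.mean())

    def to_frame(self, data: ReactionData | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"reaction_id": self.reaction_ids, "H": self.H})
        if data is not None:
            group = np.where(np.isnan(data.d), "orphan", "data")
            df["group"] = group
        return df

    def summary(self) -> dict:
        return {
            "H_Data": self.H_Data,
            "H_Orphan": self.H_Orphan,
            "H_Total": self.H_Total,
            "H_mean": self.H_mean,
            "n_bins": self.n_bins,
        }


#: Sampled ranges narrower than this are numerical noise from the solver,
#: not genuine alternative optima; matches the flux-activity threshold.
MIN_RANGE = 1e-6


def column_entropy(values: np.ndarray, n_bins: int, min_range: float = MIN_RANGE) -> float:
    """Entropy of one reaction's sampled fluxes (nats)."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo <= min_range:  # constant column: a single occupied bin
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    f = counts / counts.sum()
    f = f[f > 0]
    return float(-(f * np.log(f)).sum())


def entropy(
    sample: FluxSample,
    n_bins: int = 20,
    data: ReactionData | None = None,
    ranges: FluxRange | None = None,
    min_range: float = MIN_RANGE,
) -> EntropyReport:
    """Per-reaction and group entropies of a flux sample.

    By default each reaction is binned over its own sampled min/max; pass
    ``ranges`` to bin over externally computed (e.g. FVA) ranges instead.
    Columns whose range is below ``min_range`` count as constant (H = 0).
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if sample.n_samples == 0:
        raise ValidationError("empty flux sample")
    n = sample.matrix.shape[1]
    H = np.empty(n)
    for j in range(n):
        col = sample.matrix[:, j]
        if ranges is not None:
            lo, hi = float(ranges.minimum[j]), float(ranges.maximum[j])
            if hi - lo <= min_range:
                H[j] = 0.0
                continue
            counts, _ = np.histogram(col, bins=n_bins, range=(lo, hi))
            f = counts / max(counts.sum(), 1)
            f = f[f > 0]
            H[j] = float(-(f * np.log(f)).sum()) if f.size else 0.0
        else:
            H[j] = column_entropy(col, n_bins, min_range)
    report = EntropyReport(list(sample.reaction_ids), H, n_bins)
    if data is not None:
        report.H_Data = float(H[data.data_bounded].sum())
        report.H_Orphan = float(H[data.data_orphan].sum())
    return report


def fixed_direction(
    sample: FluxSample,
    model: MetabolicModel,
    active_tol: float = 1e-6,
) -> tuple[float | None, pd.DataFrame]:
    """Fraction of flux-carrying reversible reactions with a single sign.

    A reversible reaction qualifies if its maximum absolute sampled flux is
    at least ``active_tol``; it is *fixed* if all its sampled values above
    the threshold share one sign.  Returns ``(fraction, per-reaction
    table)``; the fraction is ``None`` when no reversible reaction carries
    flux (undefined, not zero).
    """
    rev_idx = np.flatnonzero(model.reversible)
    records = []
    n_active = n_fixed = 0
    for j in rev_idx:
        col = sample.matrix[:, j]
        active_vals = col[np.abs(col) >= active_tol]
        is_active = active_vals.size > 0
        fixed = bool(
            is_active
            and (np.all(active_vals > 0) or np.all(active_vals < 0))
        )
        n_active += is_active
        n_fixed += fixed
        records.append(
            {
                "reaction_id": model.reaction_ids[j],
                "carries_flux": is_active,
                "fixed_direction": fixed,
            }
        )
    table = pd.DataFrame(records)
    if n_active == 0:
        warnings.warn(
            "no reversible reaction carries flux; fixed-direction fraction undefined"
        )
        return None, table
    return n_fixed / n_active, table
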