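"""Uncertainty propagation from feasible sets to prediction intervals.

A prediction interval for molecule ``p`` is the [min, max] of the model
over the sampled members of a feasible set — an *inner approximation* of
the true range over the full feasible set: the model can be no more
predictive than the computed bounds, and the true interval can only be
wider.  Interval length against molecule size quantifies how extrapolation
uncertainty grows along the homologous series; for a size-extensive
property it grows linearly, and :func:`fit_linear_growth` recovers the
slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .feasibility import FeasibleSet, SampleBatch
from .qoi_data import QOITable

__all__ = [
    "PredictionInterval",
    "IntervalSeries",
    "predict_interval",
    "interval_series",
    "fit_linear_growth",
    "comparison_table",
]


class NoPredictionError(ValueError):
    """Prediction was requested from an empty feasible set."""


@dataclass(frozen=True)
class PredictionInterval:
    """Inner-approximation [lo, hi] of one prediction QOI (kcal/mol)."""

    p: int
    lo: float
    hi: float
    subset: tuple[int, ...]
    n_members: int
    inner_approximation: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")
        if self.n_members < 1:
            raise ValueError("interval must come from >= 1 member")

    @property
    def length(self) -> float:
        return self.hi - self.lo

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class IntervalSeries:
    """Interval lengths across molecule indices for one source subset."""

    p: np.ndarray
    lengths: np.ndarray
    subset: tuple[int, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=int)
        lengths = np.asarray(self.lengths, dtype=float)
        if p.shape != lengths.shape:
            raise ValueError("p/lengths shape mismatch")
        if np.any(np.diff(p) <= 0):
            raise ValueError("molecule indices must be sorted ascending")
        if np.any(lengths < 0):
            raise ValueError("interval lengths must be >= 0")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "lengths", lengths)


def _member_values(
    batch: SampleBatch, fset: FeasibleSet, p: int, model=None
) -> np.ndarray:
    """Model values of molecule ``p`` over the feasible members.

    Uses the evaluated batch column when present; otherwise evaluates the
    members on demand (lazy evaluation keeps unbounded prediction indices
    cheap — only feasible members are ever evaluated).
    """
    if fset.empty:
        raise NoPredictionError(f"feasible set {fset.indices} has no members")
    if p in batch.qoi_indices:
        return batch.column(p)[fset.members]
    if model is None:
        raise KeyError(
            f"molecule index {p} not evaluated in batch and no model given"
        )
    members = batch.params[fset.members]
    if hasattr(model, "evaluate_many"):
        return model.evaluate_many(members, [p])[:, 0]
    return np.array([model.evaluate(x, p) for x in members])


def predict_interval(
    batch: SampleBatch, fset: FeasibleSet, p: int, model=None
) -> PredictionInterval:
    """Inner-approximation interval of molecule ``p`` over a feasible set."""
    values = _member_values(batch, fset, p, model)
    return PredictionInterval(
        int(p), float(values.min()), float(values.max()), fset.indices, values.size
    )


def interval_series(
    batch: SampleBatch,
    fset: FeasibleSet,
    p_range: Iterable[int],
    model=None,
) -> IntervalSeries:
    """Per-molecule interval lengths |hi - lo| over a feasible set."""
    ps = sorted(set(int(p) for p in p_range))
    lengths = [predict_interval(batch, fset, p, model).length for p in ps]
    return IntervalSeries(np.array(ps), np.array(lengths), fset.indices)


def fit_linear_growth(
    series: IntervalSeries, p_from: int, p_to: int
) -> dict[str, float]:
    """OLS line through (p, interval length) for p in [p_from, p_to].

    Returns slope (kcal/mol per carbon), intercept, residuals' RMS and R².
    """
    sel = (series.p >= p_from) & (series.p <= p_to)
    if int(sel.sum()) < 2:
        raise ValueError("need >= 2 points in the fit range")
    x = series.p[sel].astype(float)
    y = series.lengths[sel]
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "rms_residual": float(np.sqrt(ss_res / x.size)),
        "r_squared": r2,
    }


def comparison_table(
    batch: SampleBatch,
    fset: FeasibleSet,
    table: QOITable,
    nominal_values: dict[int, float],
    p_range: Iterable[int],
    model=None,
) -> pd.DataFrame:
    """Predicted intervals vs experimental bounds and nominal predictions.

    One row per molecule: interval [lo, hi], experimental bounds when a QOI
    bound exists, the nominal model value, and two overlap flags —
    interval ∩ experimental nonempty, and nominal ∈ interval.
    """
    rows = []
    for p in sorted(set(int(p) for p in p_range)):
        interval = predict_interval(batch, fset, p, model)
        has_bound = p in table
        L = table[p].L if has_bound else np.nan
        U = table[p].U if has_bound else np.nan
        nominal = nominal_values.get(p, np.nan)
        rows.append(
            {
                "p": p,
                "lo": interval.lo,
                "hi": interval.hi,
                "length": interval.length,
                "n_members": interval.n_members,
                "L": L,
                "U": U,
                "nominal": nominal,
                "overlaps_experiment": bool(has_bound and interval.lo <= U and interval.hi >= L),
                "nominal_in_interval": bool(
                    np.isfinite(nominal) and interval.contains(nominal)
                ),
            }
        )
    return pd.DataFrame(rows)


def intervals_to_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format="%.17g")
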