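"""Construction of the prior search region.

The pipeline has no externally given parameter bounds, so the prior region
is built from the model itself:

1. per-parameter half-widths ``delta_i`` are calibrated so that moving one
   parameter from its nominal value by ``delta_i`` changes the calibration
   QOI by a target amount (default 10 kcal/mol);
2. the box ``H_k = [x_nom ± k * delta]`` provides shrinking domains for the
   surrogate-fidelity sweep;
3. a derivative-free seed optimization finds a parameter vector feasible
   for a small QOI subset; a tight box around it is sampled with a Latin
   Hypercube design; the feasible samples are PCA-rotated and extended to
   form the volume from which the production samples are drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .qoi_data import QOITable
from .synthetic_model import (
    N_PARAMS,
    PARAMETER_NAMES,
    PARAMETER_RANGES,
    ParameterVector,
    as_array,
)

__all__ = [
    "Box",
    "PriorSpec",
    "RotatedRegion",
    "SeedSearchResult",
    "CalibrationError",
    "calibrate_delta",
    "calibrate_all_deltas",
    "build_box",
    "volume_ratio",
    "find_seed_point",
    "local_box",
    "lhs_sample",
    "pca_region",
    "samples_to_csv",
    "samples_from_csv",
]


class CalibrationError(RuntimeError):
    """No perturbation within the cap produced the target QOI change."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned hyper-rectangle in parameter space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float).reshape(-1)
        upper = np.asarray(self.upper, dtype=float).reshape(-1)
        if lower.shape != upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("box bounds must be finite")
        if np.any(lower > upper):
            raise ValueError("lower must be <= upper componentwise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, X: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.all(
            (X >= self.lower - atol) & (X <= self.upper + atol), axis=1
        )

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {"lower": self.lower.tolist(), "upper": self.upper.tolist()}
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, text_or_path: Union[str, Path]) -> "Box":
        text = (
            Path(text_or_path).read_text(encoding="utf-8")
            if isinstance(text_or_path, Path) or str(text_or_path).endswith(".json")
            else str(text_or_path)
        )
        d = json.loads(text)
        return cls(np.array(d["lower"]), np.array(d["upper"]))


@dataclass(frozen=True)
class PriorSpec:
    """Nominal vector, calibrated half-widths and a shrink factor k."""

    x_nom: np.ndarray
    delta: np.ndarray
    k: float = 1.0

    def __post_init__(self) -> None:
        x_nom = np.asarray(self.x_nom, dtype=float).reshape(-1)
        delta = np.asarray(self.delta, dtype=float).reshape(-1)
        if x_nom.shape != delta.shape:
            raise ValueError("x_nom/delta shape mismatch")
        if not np.all(delta > 0):
            raise ValueError("delta must be > 0 componentwise")
        if not (0.0 < self.k <= 1.0):
            raise ValueError(f"k must be in (0, 1], got {self.k}")
        object.__setattr__(self, "x_nom", x_nom)
        object.__setattr__(self, "delta", delta)


@dataclass(frozen=True)
class RotatedRegion:
    """PCA-rotated hyper-rectangular sampling volume.

    Maps ``z in [-1, 1]^d`` to ``center + axes @ (half_widths * z)``;
    the axis columns are orthonormal.
    """

    center: np.ndarray
    axes: np.ndarray  # (d, d), columns are principal directions
    half_widths: np.ndarray

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(-1)
        axes = np.asarray(self.axes, dtype=float)
        hw = np.asarray(self.half_widths, dtype=float).reshape(-1)
        d = center.size
        if axes.shape != (d, d) or hw.shape != (d,):
            raise ValueError("inconsistent region shapes")
        if np.any(hw < 0):
            raise ValueError("half-widths must be >= 0")
        if not np.allclose(axes.T @ axes, np.eye(d), atol=1e-10):
            raise ValueError("axes must be orthonormal within 1e-10")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "half_widths", hw)

    @property
    def dim(self) -> int:
        return self.center.size

    def map_unit(self, Z: np.ndarray) -> np.ndarray:
        """Map points from the unit cube [-1, 1]^d into parameter space."""
        Z = np.atleast_2d(Z)
        return self.center + (Z * self.half_widths) @ self.axes.T

    def unmap(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        proj = (X - self.center) @ self.axes
        hw = np.where(self.half_widths > 0, self.half_widths, 1.0)
        return proj / hw

    def bounding_box(self) -> Box:
        """Tight axis-aligned box containing the rotated region."""
        reach = np.abs(self.axes) @ self.half_widths
        return Box(self.center - reach, self.center + reach)

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {
                "center": self.center.tolist(),
                "axes_row_major": self.axes.tolist(),
                "half_widths": self.half_widths.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "RotatedRegion":
        d = json.loads(text)
        return cls(
            np.array(d["center"]),
            np.array(d["axes_row_major"]),
            np.array(d["half_widths"]),
        )


@dataclass(frozen=True)
class SeedSearchResult:
    x_opt: np.ndarray
    objective: float  # kcal^2/mol^2
    feasible: bool
    n_evals: int

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


# ---------------------------------------------------------------------------
# delta calibration
# ---------------------------------------------------------------------------

def _default_cap(i: int) -> float:
    _, lo, hi = PARAMETER_RANGES[i]
    return 10.0 * (hi - lo)


def calibrate_delta(
    model,
    i: int,
    n: int = 4,
    target: float = 10.0,
    tol: float = 1e-3,
    cap: Optional[float] = None,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Half-width ``delta_i`` producing a ``target`` change in QOI ``n``.

    Positive-direction search: doubling steps find the first bracketing
    interval where ``|M_n(x_nom + u e_i) - M_n(x_nom)|`` crosses ``target``,
    then bisection refines until the achieved change is within ``tol``.

    Returns ``(delta_i, achieved_change)``.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    x_nom = as_array(model.nominal).copy()
    base = model.evaluate(x_nom, n)
    if cap is None:
        cap = _default_cap(i)

    def change(u: float) -> float:
        x = x_nom.copy()
        x[i] += u
        return abs(model.evaluate(x, n) - base)

    # doubling to find the first bracket
    u = cap / 2.0**20
    prev = 0.0
    while u < cap and change(u) < target:
        prev = u
        u *= 2.0
    u = min(u, cap)
    if change(u) < target:
        raise CalibrationError(
            f"parameter {PARAMETER_NAMES[i]!r}: no {target} kcal/mol change "
            f"within perturbation cap {cap}"
        )
    lo, hi = prev, u
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = change(mid)
        if abs(c - target) <= tol:
            return mid, c
        if c < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"parameter {PARAMETER_NAMES[i]!r}: bisection did not reach "
        f"tolerance {tol} in {max_iter} iterations"
    )


def calibrate_all_deltas(
    model,
    n: int = 4,
    target: float = 10.0,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated half-widths and achieved changes for all 27 parameters."""
    deltas = np.empty(N_PARAMS)
    achieved = np.empty(N_PARAMS)
    for i in range(N_PARAMS):
        deltas[i], achieved[i] = calibrate_delta(model, i, n=n, target=target, tol=tol)
    return deltas, achieved


def build_box(spec: PriorSpec) -> Box:
    """The shrunken prior box ``H_k = [x_nom ± k * delta]``."""
    return Box(spec.x_nom - spec.k * spec.delta, spec.x_nom + spec.k * spec.delta)


def volume_ratio(k: float, d: int) -> float:
    """Volume of H_1 relative to H_k: ``(1/k)**d``."""
    if k <= 0:
        raise ValueError("k must be > 0")
    if d < 1:
        raise ValueError("d must be >= 1")
    return (1.0 / k) ** d


# ---------------------------------------------------------------------------
# seed optimization and local sampling
# ---------------------------------------------------------------------------

def find_seed_point(
    model,
    table: QOITable,
    subset: Iterable[int],
    start: Optional[Union[ParameterVector, np.ndarray]] = None,
    budget: int = 5000,
) -> SeedSearchResult:
    """Minimize the squared residual to the reported values over a subset.

    Gradient-free simplex search from ``start`` (default: the nominal),
    best-found semantics: exhausting the budget is not an error.  The
    feasibility flag is true iff every residual magnitude is within the
    reported uncertainty.
    """
    subset = sorted(set(int(e) for e in subset))
    if not subset:
        raise ValueError("subset must be nonempty")
    if budget <= 0:
        raise ValueError("budget must be > 0")
    x0 = as_array(start) if start is not None else as_array(model.nominal)
    values = np.array([table[e].value for e in subset])
    uncertainties = np.array([table[e].uncertainty for e in subset])
    n_evals = 0

    def residuals(x: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        return np.array([model.evaluate(x, e) for e in subset]) - values

    def objective(x: np.ndarray) -> float:
        r = residuals(x)
        return float(r @ r)

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxfev": budget, "xatol": 1e-10, "fatol": 1e-12, "adaptive": True},
    )
    best_x, best_f = (res.x, float(res.fun))
    f0 = objective(x0)
    if f0 < best_f:  # simplex result can never beat its start by less than 0
        best_x, best_f = x0, f0
    r = residuals(best_x)
    feasible = bool(np.all(np.abs(r) <= uncertainties))
    return SeedSearchResult(best_x.copy(), best_f, feasible, n_evals)


def local_box(
    x_opt: Union[ParameterVector, np.ndarray], rel: float = 1e-3
) -> Box:
    """Tight box ``[x_opt ± |x_opt| * rel]`` around a seed point.

    A zero component would get zero width under the multiplicative rule;
    it falls back to ``rel * median(|x_opt|)`` (or ``rel`` if the whole
    vector is zero).
    """
    if rel <= 0:
        raise ValueError("rel must be > 0")
    x = as_array(x_opt)
    hw = np.abs(x) * rel
    if np.any(hw == 0):
        med = float(np.median(np.abs(x)))
        hw = np.where(hw == 0, rel * med if med > 0 else rel, hw)
    return Box(x - hw, x + hw)


# ---------------------------------------------------------------------------
# Latin Hypercube sampling and PCA rotation
# ---------------------------------------------------------------------------

def lhs_sample(
    region: Union[Box, RotatedRegion], N: int, seed: int
) -> np.ndarray:
    """N Latin-Hypercube samples inside a box or rotated region.

    One sample per equal-probability stratum per dimension; deterministic
    given the seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    d = region.dim
    unit = qmc.LatinHypercube(d=d, seed=int(seed)).random(N)
    if isinstance(region, Box):
        return qmc.scale(unit, region.lower, region.upper)
    return region.map_unit(2.0 * unit - 1.0)


def pca_region(
    feasible_samples: np.ndarray,
    extension: float = 10.0,
    floor: float = 1e-12,
    on_deficient: str = "fallback",
) -> RotatedRegion:
    """Rotated region around a cloud of feasible samples.

    Center = sample mean; axes = principal directions (all components
    preserved); half-widths = ``extension`` x the per-axis maximum absolute
    projection of the centered samples, floored at ``floor`` so that
    rank-deficient clouds still span a usable volume.

    With fewer than dim+1 samples the directions are not fully determined;
    ``on_deficient`` selects between the floored fallback and an error.
    """
    X = np.atleast_2d(np.asarray(feasible_samples, dtype=float))
    n, d = X.shape
    if n < d + 1:
        if on_deficient == "error":
            raise ValueError(f"need >= {d + 1} samples for a full PCA, got {n}")
    center = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - center, full_matrices=True)
    axes = vt.T  # columns = principal directions, all preserved
    # deterministic sign convention: largest-|.| component of each axis > 0
    for j in range(d):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    proj = np.abs((X - center) @ axes)
    hw = extension * proj.max(axis=0)
    hw = np.maximum(hw, floor)
    return RotatedRegion(center, axes, hw)


# ---------------------------------------------------------------------------
# sample matrix persistence
# ---------------------------------------------------------------------------

def samples_to_csv(X: np.ndarray, path: Union[str, Path]) -> None:
    X = np.atleast_2d(X)
    if X.shape[1] != N_PARAMS:
        raise ValueError(f"expected {N_PARAMS} columns, got {X.shape[1]}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(PARAMETER_NAMES) + "\n")
        for row in X:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def samples_from_csv(path: Union[str, Path]) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != list(PARAMETER_NAMES):
        raise ValueError(f"{path}: header does not match parameter names")
    return df.to_numpy(dtype=float)
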