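"""Surrogate-fidelity diagnostics on shrinking domains.

A quadratic response surface (406 coefficients in 27 dimensions) is fit to
the property model on the box ``H_k = [x_nom ± k * delta]`` and its
cross-validated fitting error — the absolute difference between a model
evaluation and a surrogate evaluation on held-out points — is swept over a
shrinking sequence of k.  The sweep locates the largest domain on which a
surrogate is accurate to within the experimental uncertainty of the
calibration QOI; if that domain is a tiny fraction of the prior volume,
surrogate-based analysis is hopeless and direct sampling is the only
option.

The error statistic plotted by convention here is the mean over folds of
the fold-maximum absolute error (conservative); the mean-absolute and
max-absolute variants are recorded alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from ._rng import substream
from .prior_region import Box, PriorSpec, build_box, lhs_sample, volume_ratio
from .qoi_data import QOITable

logger = logging.getLogger(__name__)

__all__ = [
    "QuadraticSurrogate",
    "FidelityCurve",
    "CVError",
    "UnderdeterminedError",
    "n_quadratic_coefficients",
    "fit_quadratic",
    "cv_fit_error",
    "shrink_sweep",
]


class UnderdeterminedError(ValueError):
    """Fewer samples than quadratic coefficients."""


def n_quadratic_coefficients(d: int) -> int:
    """Full quadratic in d variables: (d+1)(d+2)/2 coefficients."""
    return (d + 1) * (d + 2) // 2


def _features(U: np.ndarray) -> np.ndarray:
    """Design matrix [1, u_i, u_i^2, u_i u_j (i<j)] in the standardized basis."""
    n, d = U.shape
    iu, ju = np.triu_indices(d, k=1)
    return np.hstack([np.ones((n, 1)), U, U**2, U[:, iu] * U[:, ju]])


@dataclass(frozen=True)
class QuadraticSurrogate:
    """Least-squares quadratic response surface on a box domain.

    Coefficients are stored in the domain-standardized basis
    ``u = (x - center) / half_width`` in [-1, 1]^d; evaluation outside the
    fit domain is flagged by :meth:`inside`.
    """

    domain: Box
    coef: np.ndarray          # standardized basis, length (d+1)(d+2)/2
    residual_norm: float
    rank: int

    @property
    def dim(self) -> int:
        return self.domain.dim

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        center = 0.5 * (self.domain.lower + self.domain.upper)
        half = np.maximum(0.5 * (self.domain.upper - self.domain.lower), 1e-300)
        return (np.atleast_2d(X) - center) / half

    def inside(self, X: np.ndarray) -> np.ndarray:
        return self.domain.contains(X)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return _features(self._standardize(X)) @ self.coef

    def raw_coefficients(self) -> dict[str, np.ndarray]:
        """Coefficients re-expressed for raw (unstandardized) inputs."""
        d = self.dim
        center = 0.5 * (self.domain.lower + self.domain.upper)
        half = 0.5 * (self.domain.upper - self.domain.lower)
        c0 = float(self.coef[0])
        lin_s = self.coef[1 : 1 + d]
        diag_s = self.coef[1 + d : 1 + 2 * d]
        iu, ju = np.triu_indices(d, k=1)
        Q = np.zeros((d, d))
        Q[np.arange(d), np.arange(d)] = diag_s
        Q[iu, ju] = Q[ju, iu] = 0.5 * self.coef[1 + 2 * d :]
        # u = (x - c)/h  =>  expand in x
        Hinv = 1.0 / half
        Qx = Q * np.outer(Hinv, Hinv)
        lin_x = lin_s * Hinv - 2.0 * Qx @ center
        const = c0 - float(lin_s * Hinv @ center) + float(center @ Qx @ center)
        return {"intercept": np.array(const), "linear": lin_x, "quadratic": Qx}

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {
                "domain": {"lower": self.domain.lower.tolist(),
                           "upper": self.domain.upper.tolist()},
                "coef_standardized": self.coef.tolist(),
                "residual_norm": self.residual_norm,
                "rank": self.rank,
            }
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def fit_quadratic(X: np.ndarray, y: np.ndarray, domain: Box) -> QuadraticSurrogate:
    """Least-squares quadratic fit on inputs standardized to the domain box.

    Requires at least as many rows as coefficients; a rank-deficient system
    falls back to the minimum-norm solution with a logged warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    n, d = X.shape
    p = n_quadratic_coefficients(d)
    if n < p:
        raise UnderdeterminedError(f"need >= {p} rows to fit, got {n}")
    center = 0.5 * (domain.lower + domain.upper)
    half = np.maximum(0.5 * (domain.upper - domain.lower), 1e-300)
    F = _features((X - center) / half)
    coef, res, rank, _ = np.linalg.lstsq(F, y, rcond=None)
    if rank < p:
        logger.warning("rank-deficient quadratic fit (rank %d < %d); minimum-norm solution used", rank, p)
    resid_norm = float(np.linalg.norm(F @ coef - y))
    return QuadraticSurrogate(domain, coef, resid_norm, int(rank))


@dataclass(frozen=True)
class CVError:
    """Cross-validated surrogate fitting error, kcal/mol."""

    k: float
    mean_abs: float
    max_abs: float
    fold_max_mean: float
    fold_max: tuple[float, ...]
    n_samples: int
    folds: int
    seed: int

    @property
    def error(self) -> float:
        """Headline statistic: mean over folds of the fold-maximum error."""
        return self.fold_max_mean

    @property
    def fold_max_se(self) -> float:
        """Standard error of the fold maxima around their mean."""
        fm = np.array(self.fold_max)
        return float(fm.std(ddof=1) / np.sqrt(fm.size)) if fm.size > 1 else 0.0


def cv_fit_error(
    model,
    spec: PriorSpec,
    k: float,
    N: int = 7500,
    folds: int = 10,
    seed: int = 0,
    n: int = 4,
) -> CVError:
    """K-fold cross-validated quadratic fitting error on the domain H_k.

    Latin-Hypercube samples are drawn in ``H_k``; per fold, the surrogate is
    fit on the training rows and the held-out absolute differences
    |model - surrogate| are collected.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    box = build_box(replace(spec, k=float(k)))
    sample_seed = substream(seed, f"fidelity-samples-k={k!r}").integers(2**31)
    X = lhs_sample(box, N, int(sample_seed))
    if hasattr(model, "evaluate_many"):
        y = model.evaluate_many(X, [n])[:, 0]
    else:
        y = np.array([model.evaluate(x, n) for x in X])

    order = substream(seed, f"fidelity-folds-k={k!r}").permutation(N)
    fold_of = np.empty(N, dtype=int)
    fold_of[order] = np.arange(N) % folds

    p = n_quadratic_coefficients(X.shape[1])
    abs_errors = []
    fold_max = []
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if int(train.sum()) < p:
            raise UnderdeterminedError(
                f"k={k}: fold {f} has {int(train.sum())} training rows < {p} coefficients"
            )
        surrogate = fit_quadratic(X[train], y[train], box)
        err = np.abs(y[test] - surrogate(X[test]))
        abs_errors.append(err)
        fold_max.append(float(err.max()))
    all_err = np.concatenate(abs_errors)
    return CVError(
        k=float(k),
        mean_abs=float(all_err.mean()),
        max_abs=float(all_err.max()),
        fold_max_mean=float(np.mean(fold_max)),
        fold_max=tuple(fold_max),
        n_samples=N,
        folds=folds,
        seed=int(seed),
    )


@dataclass(frozen=True)
class FidelityCurve:
    """Surrogate fitting error vs shrink factor k."""

    k: np.ndarray
    errors: np.ndarray
    statistic: str
    details: tuple[CVError, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        errors = np.asarray(self.errors, dtype=float)
        if np.any((k <= 0) | (k > 1)):
            raise ValueError("k values must be in (0, 1]")
        if np.any(np.diff(k) <= 0):
            raise ValueError("k values must be sorted ascending")
        if np.any(errors < 0):
            raise ValueError("errors must be >= 0")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "errors", errors)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("k,fold_max_mean,mean_abs,max_abs,n_samples,folds,seed\n")
            for cv in self.details:
                fh.write(
                    f"{cv.k!r},{cv.fold_max_mean!r},{cv.mean_abs!r},"
                    f"{cv.max_abs!r},{cv.n_samples},{cv.folds},{cv.seed}\n"
                )


def shrink_sweep(
    model,
    spec: PriorSpec,
    k_list: Sequence[float],
    table: QOITable,
    n: int = 4,
    N: int = 7500,
    folds: int = 10,
    seed: int = 0,
) -> tuple[FidelityCurve, dict]:
    """Fidelity curve over shrinking domains plus the threshold shrink k*.

    ``k*`` is the largest k whose error is at or below the experimental
    uncertainty of QOI ``n``; the volume ratio of the prior box to ``H_k*``
    is attached to the report.  ``k*`` is None when no k qualifies.
    """
    ks = sorted(float(k) for k in k_list)
    if any(not (0 < k <= 1) for k in ks):
        raise ValueError("k values must lie in (0, 1]")
    details = tuple(
        cv_fit_error(model, spec, k, N=N, folds=folds, seed=seed, n=n) for k in ks
    )
    curve = FidelityCurve(
        np.array(ks), np.array([cv.error for cv in details]), "fold_max_mean", details
    )
    threshold = table[n].uncertainty
    passing = [k for k, e in zip(curve.k, curve.errors) if e <= threshold]
    k_star = max(passing) if passing else None
    report = {
        "qoi": int(n),
        "threshold_kcal_mol": threshold,
        "k_star": k_star,
        "volume_ratio": volume_ratio(k_star, spec.x_nom.size) if k_star else None,
    }
    return curve, report
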