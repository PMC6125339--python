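"""Direct-sampling feasibility analysis.

A batch of sampled parameter vectors is evaluated for every QOI, masked
against the experimental bounds (closed intervals, exact comparison), and
queried for feasible subsets: intersections over QOI index sets, count
cascades, the longest consecutive feasible run, and consistency verdicts.
A sampled witness proves consistency; an empty sampled intersection is
evidence of inconsistency, never proof.

Also here: the evolutionary fallback search for subsets where plain
sampling finds nothing, and the line-segment probes used to demonstrate
feasible-set non-convexity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._rng import substream
from .qoi_data import QOITable
from .prior_region import Box, RotatedRegion
from .synthetic_model import N_PARAMS, PARAMETER_NAMES, as_array

logger = logging.getLogger(__name__)

__all__ = [
    "SampleBatch",
    "FeasibleSet",
    "SegmentScan",
    "ConsistencyVerdict",
    "evaluate_batch",
    "apply_bounds",
    "feasible_subset",
    "count_at_least",
    "longest_consecutive_feasible",
    "consistency_verdict",
    "ga_search",
    "segment_scan",
    "convexity_check",
    "find_nonconvex_pair",
    "batch_to_csv",
    "batch_from_csv",
]


@dataclass(frozen=True)
class SampleBatch:
    """Sampled parameter vectors with QOI evaluations and feasibility mask.

    ``ok`` flags rows whose model evaluations all succeeded; failed rows are
    kept (with NaN QOIs) for row-id stability but excluded from every
    downstream count and membership query.  ``mask`` is filled by
    :func:`apply_bounds` and is aligned with ``mask_indices``.
    """

    params: np.ndarray            # (N, 27)
    qoi_indices: tuple[int, ...]  # molecule indices of the qois columns
    qois: np.ndarray              # (N, m), kcal/mol
    ok: np.ndarray                # (N,) bool
    mask: Optional[np.ndarray] = None            # (N, m_masked) bool
    mask_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.params.shape[0] != self.qois.shape[0] != self.ok.shape[0]:
            raise ValueError("row counts differ across fields")
        if self.qois.shape[1] != len(self.qoi_indices):
            raise ValueError("qois column count does not match qoi_indices")
        if self.mask is not None and self.mask.shape != (
            self.params.shape[0],
            len(self.mask_indices),
        ):
            raise ValueError("mask shape does not match mask_indices")

    @property
    def n_rows(self) -> int:
        return self.params.shape[0]

    def column(self, e: int) -> np.ndarray:
        try:
            j = self.qoi_indices.index(e)
        except ValueError:
            raise KeyError(f"QOI column for molecule index {e} not evaluated") from None
        return self.qois[:, j]

    def mask_column(self, e: int) -> np.ndarray:
        if self.mask is None:
            raise ValueError("batch has no mask; call apply_bounds first")
        try:
            j = self.mask_indices.index(e)
        except ValueError:
            raise KeyError(f"no feasibility mask for molecule index {e}") from None
        return self.mask[:, j]


@dataclass(frozen=True)
class FeasibleSet:
    """Member rows of a batch feasible for every QOI in ``indices``."""

    indices: tuple[int, ...]
    members: np.ndarray  # row indices into the batch

    @property
    def n_members(self) -> int:
        return self.members.size

    @property
    def empty(self) -> bool:
        return self.members.size == 0


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Sampling-based consistency verdict for a QOI subset.

    ``evidence_of_consistency`` iff at least one sampled member satisfies
    every bound in the subset.  The negative verdict is sample-limited: it
    does not prove that no feasible parameter vector exists.
    """

    subset: tuple[int, ...]
    evidence_of_consistency: bool
    n_members: int
    note: str = ""

    @property
    def label(self) -> str:
        return "evidence_of_consistency" if self.evidence_of_consistency else "no_evidence"


def evaluate_batch(
    model,
    samples: np.ndarray,
    indices: Sequence[int],
    chunk_size: Optional[int] = None,
) -> SampleBatch:
    """Evaluate every sample for every molecule index (mask left empty).

    Results are independent of evaluation order and chunking.  Rows whose
    evaluation raises are flagged not-ok, logged, and excluded downstream.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    indices = tuple(int(n) for n in indices)
    if not indices:
        raise ValueError("molecule index list must be nonempty")
    if any(n < 1 for n in indices):
        raise ValueError("molecule indices must be >= 1")
    N = X.shape[0]
    qois = np.full((N, len(indices)), np.nan)
    ok = np.ones(N, dtype=bool)

    rows = range(N)
    if chunk_size is None:
        chunk_size = N
    for start in range(0, N, chunk_size):
        stop = min(start + chunk_size, N)
        chunk = X[start:stop]
        if hasattr(model, "evaluate_many"):
            try:
                qois[start:stop] = model.evaluate_many(chunk, indices)
                continue
            except Exception:
                pass  # fall through to per-row evaluation
        for r in range(start, stop):
            for j, n in enumerate(indices):
                try:
                    qois[r, j] = model.evaluate(X[r], n)
                except Exception as exc:
                    ok[r] = False
                    logger.warning("evaluation failed for row %d, n=%d: %s", r, n, exc)
                    break
    bad = np.where(~np.all(np.isfinite(qois), axis=1))[0]
    if bad.size:
        ok[bad] = False
    n_failed = int(np.sum(~ok))
    if n_failed:
        logger.info("excluded %d of %d rows after evaluation failures", n_failed, N)
    return SampleBatch(X, indices, qois, ok)


def apply_bounds(batch: SampleBatch, table: QOITable) -> SampleBatch:
    """Fill the feasibility mask: closed-interval rule, exact comparison."""
    missing = [e for e in table.indices if e not in batch.qoi_indices]
    if missing:
        raise KeyError(f"batch lacks QOI columns for indices {missing}")
    cols = []
    for bound in table:
        q = batch.column(bound.index)
        cols.append((q >= bound.L) & (q <= bound.U))
    mask = np.column_stack(cols)
    mask[~batch.ok] = False
    return replace(batch, mask=mask, mask_indices=table.indices)


def feasible_subset(batch: SampleBatch, I: Iterable[int]) -> FeasibleSet:
    """Rows feasible for every QOI in ``I`` (intersection of the F_e)."""
    I = tuple(sorted(set(int(e) for e in I)))
    if not I:
        raise ValueError("subset must be nonempty")
    conj = batch.ok.copy()
    for e in I:
        conj &= batch.mask_column(e)
    return FeasibleSet(I, np.where(conj)[0])


def count_at_least(batch: SampleBatch, m: int) -> int:
    """Rows feasible for at least ``m`` QOIs; non-increasing in ``m``."""
    if batch.mask is None:
        raise ValueError("batch has no mask; call apply_bounds first")
    if not 1 <= m <= len(batch.mask_indices):
        raise ValueError(f"m must be in [1, {len(batch.mask_indices)}], got {m}")
    rowsum = batch.mask.sum(axis=1)
    return int(np.sum((rowsum >= m) & batch.ok))


def longest_consecutive_feasible(
    batch: SampleBatch, table: QOITable
) -> Optional[FeasibleSet]:
    """Longest consecutive index run with a nonempty sampled feasible set.

    Ties break toward the smallest starting index.  Returns None when no
    single QOI has a feasible row.
    """
    if batch.mask is None:
        raise ValueError("batch has no mask; call apply_bounds first")
    indices = table.indices
    best: Optional[FeasibleSet] = None
    for ai, a in enumerate(indices):
        for bi in range(len(indices) - 1, ai - 1, -1):
            b = indices[bi]
            run = list(range(a, b + 1))
            if any(e not in table for e in run):
                continue
            if best is not None and len(run) <= len(best.indices):
                break  # shorter runs from this start cannot win
            fs = feasible_subset(batch, run)
            if not fs.empty:
                if best is None or len(run) > len(best.indices):
                    best = fs
                break
    return best


def consistency_verdict(batch: SampleBatch, I: Iterable[int]) -> ConsistencyVerdict:
    fs = feasible_subset(batch, I)
    if fs.empty:
        note = (
            "sample-limited: the absence of a sampled witness does not prove "
            "the non-existence of a feasible point"
        )
        return ConsistencyVerdict(fs.indices, False, 0, note)
    return ConsistencyVerdict(fs.indices, True, fs.n_members)


# ---------------------------------------------------------------------------
# evolutionary fallback search
# ---------------------------------------------------------------------------

def _max_violation(
    model, X: np.ndarray, subset: Sequence[int], table: QOITable
) -> np.ndarray:
    """Worst bound violation per row, normalized by the QOI uncertainty.

    <= 0 exactly when the row is feasible for every QOI in the subset.
    """
    if hasattr(model, "evaluate_many"):
        Q = model.evaluate_many(X, subset)
    else:
        Q = np.array([[model.evaluate(x, e) for e in subset] for x in np.atleast_2d(X)])
    out = np.full(Q.shape[0], -np.inf)
    for j, e in enumerate(subset):
        b = table[e]
        v = np.maximum(b.L - Q[:, j], Q[:, j] - b.U) / b.uncertainty
        out = np.maximum(out, v)
    return out


@dataclass(frozen=True)
class GASearchResult:
    x: np.ndarray
    violation: float  # worst normalized violation; <= 0 iff feasible
    n_evals: int

    @property
    def feasible(self) -> bool:
        return self.violation <= 0.0


def ga_search(
    model,
    table: QOITable,
    subset: Iterable[int],
    region: Union[Box, RotatedRegion],
    budget: int = 20000,
    seed: int = 0,
    population: int = 50,
    tournament: int = 3,
    mutation_scale: float = 0.15,
    crossover_rate: float = 0.7,
) -> GASearchResult:
    """Genetic-algorithm search for a feasible point of a QOI subset.

    Minimizes the worst uncertainty-normalized bound violation over the
    subset (scale-free across QOIs); elitism 1, tournament selection,
    Gaussian mutation scaled to the region half-widths.  Deterministic for
    a fixed seed; best-found semantics (never raises on budget exhaustion).
    """
    subset = sorted(set(int(e) for e in subset))
    if budget <= 0:
        raise ValueError("budget must be > 0")
    rng = np.random.default_rng(int(seed))

    if isinstance(region, Box):
        center = 0.5 * (region.lower + region.upper)
        half = 0.5 * (region.upper - region.lower)

        def to_x(Z: np.ndarray) -> np.ndarray:
            return center + Z * half
    else:
        def to_x(Z: np.ndarray) -> np.ndarray:
            return region.map_unit(Z)

    d = region.dim
    pop = rng.uniform(-1.0, 1.0, size=(min(population, budget), d))
    fit = _max_violation(model, to_x(pop), subset, table)
    n_evals = pop.shape[0]
    best_i = int(np.argmin(fit))
    best_z, best_f = pop[best_i].copy(), float(fit[best_i])

    while n_evals < budget and best_f > 0.0:
        n_children = min(population, budget - n_evals)
        children = np.empty((n_children, d))
        for c in range(n_children):
            # tournament selection of two parents
            cand = rng.integers(0, pop.shape[0], size=tournament)
            p1 = pop[cand[np.argmin(fit[cand])]]
            cand = rng.integers(0, pop.shape[0], size=tournament)
            p2 = pop[cand[np.argmin(fit[cand])]]
            child = np.where(rng.random(d) < 0.5, p1, p2) if rng.random() < crossover_rate else p1.copy()
            child = child + rng.normal(0.0, mutation_scale, size=d)
            children[c] = np.clip(child, -1.0, 1.0)
        children[0] = best_z  # elitism
        child_fit = _max_violation(model, to_x(children), subset, table)
        n_evals += n_children
        pop, fit = children, child_fit
        i = int(np.argmin(fit))
        if float(fit[i]) < best_f:
            best_z, best_f = pop[i].copy(), float(fit[i])

    return GASearchResult(to_x(best_z[None, :])[0], best_f, n_evals)


# ---------------------------------------------------------------------------
# line-segment geometry probes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentScan:
    """Feasibility of one QOI along the segment x(t) = (1-t) x1 + t x2."""

    x1: np.ndarray
    x2: np.ndarray
    qoi: int
    t: np.ndarray
    values: np.ndarray
    feasible: np.ndarray
    crossings: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t grid must be strictly increasing")

    def point(self, t: float) -> np.ndarray:
        return (1.0 - t) * self.x1 + t * self.x2


def segment_scan(
    model,
    x1: np.ndarray,
    x2: np.ndarray,
    n: int,
    table: QOITable,
    t_lo: float = 0.0,
    t_hi: float = 1.0,
    step: float = 1e-3,
    refine_tol: float = 1e-6,
) -> SegmentScan:
    """Evaluate one QOI along a parameter-space line segment.

    The grid spans [t_lo, t_hi] with spacing <= ``step`` (endpoints, and
    t = 0 and t = 1 when inside the range, are always included).  Boundary
    crossings between adjacent grid points are refined by bisection to
    |dt| <= ``refine_tol`` and returned separately.
    """
    if not t_lo < t_hi:
        raise ValueError("t_lo must be < t_hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    x1 = as_array(x1).astype(float)
    x2 = as_array(x2).astype(float)
    bound = table[n]

    n_steps = max(int(np.ceil((t_hi - t_lo) / step)), 1)
    grid = np.linspace(t_lo, t_hi, n_steps + 1)
    for anchor in (0.0, 1.0):
        if t_lo <= anchor <= t_hi and not np.any(np.isclose(grid, anchor, atol=1e-15)):
            grid = np.sort(np.append(grid, anchor))

    def value(t: float) -> float:
        return model.evaluate((1.0 - t) * x1 + t * x2, n)

    if hasattr(model, "evaluate_many"):
        pts = (1.0 - grid[:, None]) * x1 + grid[:, None] * x2
        vals = model.evaluate_many(pts, [n])[:, 0]
    else:
        vals = np.array([value(t) for t in grid])
    feas = (vals >= bound.L) & (vals <= bound.U)

    crossings = []
    for i in range(len(grid) - 1):
        if feas[i] == feas[i + 1]:
            continue
        lo, hi = grid[i], grid[i + 1]
        lo_feas = bool(feas[i])
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if bound.contains(value(mid)) == lo_feas:
                lo = mid
            else:
                hi = mid
        crossings.append(0.5 * (lo + hi))
    return SegmentScan(x1, x2, int(n), grid, vals, feas, tuple(crossings))


def convexity_check(scan: SegmentScan) -> str:
    """'non_convex' iff an interior grid point of (0, 1) is infeasible.

    Both endpoints (t = 0 and t = 1) must be feasible; an infeasible
    interior point then certifies that the feasible set is non-convex.
    """
    for anchor in (0.0, 1.0):
        j = int(np.argmin(np.abs(scan.t - anchor)))
        if not np.isclose(scan.t[j], anchor, atol=1e-12):
            raise ValueError(f"scan grid does not contain t = {anchor}")
        if not scan.feasible[j]:
            raise ValueError(f"endpoint t = {anchor} is not feasible")
    interior = (scan.t > 0.0) & (scan.t < 1.0)
    return "non_convex" if np.any(~scan.feasible[interior]) else "convex_consistent"


def find_nonconvex_pair(
    model,
    table: QOITable,
    n: int = 6,
    seed: int = 0,
    max_tries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Search for two feasible points of one QOI with an infeasible gap.

    Walks lines through a feasible point along directions that swing the
    synthetic model's sinusoid by a full period while canceling the linear
    drift of the QOI, then picks two feasible points separated by an
    infeasible stretch.  Returns (x1, x2); raises if no pair is found.
    """
    from .synthetic_model import lp_feasibility_oracle, coefficient_box, solve_for_coefficients

    cfg = model.cfg
    verdict = lp_feasibility_oracle(table, [n], coefficient_box(cfg), interior=True)
    if not verdict.feasible:
        raise ValueError(f"QOI {n} admits no feasible point over the design box")
    x_center = solve_for_coefficients(verdict.witness, cfg)

    rng = substream(seed, "nonconvex-probe")
    L = cfg.w_alpha + (n - 1) * cfg.w_beta + (1.0 / n - 1.0) * cfg.w_gamma
    for attempt in range(max_tries):
        d = np.sign(cfg.omega) + 0.3 * rng.standard_normal(N_PARAMS)
        d -= L * (L @ d) / (L @ L)          # cancel the linear QOI drift
        swing = float(cfg.omega @ d)
        if abs(swing) < 1e-9:
            continue
        d *= (2.0 * np.pi) / swing          # one full sinusoid period per unit t
        x_far = x_center + d * cfg.delta_ref
        scan = segment_scan(model, x_center, x_far, n, table, t_lo=-1.5, t_hi=1.5,
                            step=2e-3)
        feas_idx = np.where(scan.feasible)[0]
        if feas_idx.size < 2:
            continue
        # look for two feasible grid points with an infeasible stretch between
        gaps = np.where(np.diff(feas_idx) > 1)[0]
        for g in gaps:
            i1, i2 = feas_idx[g], feas_idx[g + 1]
            x1 = scan.point(float(scan.t[i1]))
            x2 = scan.point(float(scan.t[i2]))
            check = segment_scan(model, x1, x2, n, table, step=2e-3)
            if convexity_check(check) == "non_convex":
                return x1, x2
    raise RuntimeError(f"no non-convex pair found for QOI {n} in {max_tries} tries")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def batch_to_csv(batch: SampleBatch, directory: Union[str, Path], stem: str = "batch") -> dict[str, Path]:
    """Persist a batch as params/qois/mask CSVs sharing a row_id column."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    row_id = np.arange(batch.n_rows)
    paths = {}

    def _write(name: str, columns: Sequence[str], matrix: np.ndarray, fmt) -> None:
        path = directory / f"{stem}_{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("row_id," + ",".join(columns) + "\n")
            for r, row in zip(row_id, matrix):
                fh.write(str(r) + "," + ",".join(fmt(v) for v in row) + "\n")
        paths[name] = path

    _write("params", PARAMETER_NAMES, batch.params, lambda v: repr(float(v)))
    qcols = [f"M{e}" for e in batch.qoi_indices]
    _write("qois", qcols, batch.qois, lambda v: repr(float(v)))
    if batch.mask is not None:
        mcols = [f"M{e}" for e in batch.mask_indices]
        _write("mask", mcols, batch.mask.astype(int), lambda v: str(int(v)))
    return paths


def batch_from_csv(directory: Union[str, Path], stem: str = "batch") -> SampleBatch:
    directory = Path(directory)
    read = lambda name: pd.read_csv(directory / f"{stem}_{name}.csv", float_precision="round_trip")
    params = read("params")
    qois = read("qois")
    qoi_indices = tuple(int(c[1:]) for c in qois.columns if c != "row_id")
    mask = None
    mask_indices: tuple[int, ...] = ()
    mask_path = directory / f"{stem}_mask.csv"
    if mask_path.exists():
        mdf = read("mask")
        mask_indices = tuple(int(c[1:]) for c in mdf.columns if c != "row_id")
        mask = mdf.drop(columns="row_id").to_numpy(dtype=bool)
    X = params.drop(columns="row_id").to_numpy(dtype=float)
    Q = qois.drop(columns="row_id").to_numpy(dtype=float)
    ok = np.all(np.isfinite(Q), axis=1)
    return SampleBatch(X, qoi_indices, Q, ok, mask, mask_indices)
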