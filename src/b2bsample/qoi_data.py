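"""Experimental quantities of interest and their uncertainty bounds.

The default data set is the heat of formation (kcal/mol, 298 K) of the
linear alkanes methane through octane, with 95%-confidence half-widths
from the thermochemical-network reference values.  Each QOI is indexed by
the carbon count of the alkane; carbon counts without a reported bound
(nonane and beyond) are prediction-only indices and carry no ``QOIBound``.

Bounds are closed intervals: a model evaluation landing exactly on L or U
counts as feasible.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd

__all__ = [
    "QOIBound",
    "QOITable",
    "InvalidBoundError",
    "bounds_from_value",
    "load_qoi_table",
    "relax_bounds",
    "DEFAULT_QOI_ROWS",
]

#: Reported heat of formation and 95%-CI half-width per carbon count,
#: methane (1) through octane (8), kcal/mol.
DEFAULT_QOI_ROWS: tuple[tuple[int, float, float], ...] = (
    (1, -17.81, 0.01),
    (2, -20.06, 0.03),
    (3, -25.10, 0.05),
    (4, -30.10, 0.06),
    (5, -34.98, 0.07),
    (6, -39.90, 0.08),
    (7, -44.82, 0.11),
    (8, -49.78, 0.16),
)


class InvalidBoundError(ValueError):
    """Raised for non-positive uncertainties or malformed bound tables."""


def bounds_from_value(value: float, uncertainty: float) -> tuple[float, float]:
    """Turn ``value ± uncertainty`` into a closed interval (L, U).

    Parameters
    ----------
    value : float
        Reported quantity, kcal/mol.
    uncertainty : float
        95%-CI half-width, kcal/mol; must be > 0.
    """
    if not uncertainty > 0:
        raise InvalidBoundError(f"uncertainty must be > 0, got {uncertainty!r}")
    return value - uncertainty, value + uncertainty


@dataclass(frozen=True)
class QOIBound:
    """One experimental datum: index (carbon count), value and half-width."""

    index: int
    value: float
    uncertainty: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidBoundError(f"QOI index must be >= 1, got {self.index}")
        if not self.uncertainty > 0:
            raise InvalidBoundError(
                f"uncertainty must be > 0 for index {self.index}, "
                f"got {self.uncertainty!r}"
            )

    @property
    def L(self) -> float:
        return self.value - self.uncertainty

    @property
    def U(self) -> float:
        return self.value + self.uncertainty

    def contains(self, x: float) -> bool:
        """Closed-interval membership: L <= x <= U."""
        return self.L <= x <= self.U


class QOITable:
    """Ordered, uniquely indexed collection of :class:`QOIBound` (kcal/mol)."""

    units = "kcal/mol"

    def __init__(self, bounds: Iterable[QOIBound]):
        bounds = sorted(bounds, key=lambda b: b.index)
        if not bounds:
            raise InvalidBoundError("QOI table must be nonempty")
        indices = [b.index for b in bounds]
        if len(set(indices)) != len(indices):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise InvalidBoundError(f"duplicate QOI indices: {dupes}")
        self._bounds = tuple(bounds)
        self._by_index = {b.index: b for b in self._bounds}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._bounds)

    def __iter__(self) -> Iterator[QOIBound]:
        return iter(self._bounds)

    def __getitem__(self, index: int) -> QOIBound:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no QOI bound for index {index}") from None

    def __contains__(self, index: int) -> bool:
        return index in self._by_index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QOITable) and self._bounds == other._bounds

    def __repr__(self) -> str:
        return f"QOITable({len(self)} bounds, indices {self.indices})"

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(b.index for b in self._bounds)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(b.value for b in self._bounds)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [b.index for b in self._bounds],
                "value": [b.value for b in self._bounds],
                "uncertainty": [b.uncertainty for b in self._bounds],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        # repr-based float formatting keeps a write/read cycle bit-exact
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("index,value,uncertainty\n")
            for b in self._bounds:
                fh.write(f"{b.index},{b.value!r},{b.uncertainty!r}\n")

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(
            {
                "units": self.units,
                "bounds": [
                    {
                        "index": b.index,
                        "value": b.value,
                        "uncertainty": b.uncertainty,
                        "L": b.L,
                        "U": b.U,
                    }
                    for b in self._bounds
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def _table_from_frame(df: pd.DataFrame, source: str) -> QOITable:
    required = {"index", "value", "uncertainty"}
    if not required.issubset(df.columns):
        raise InvalidBoundError(
            f"{source}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bounds = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            bounds.append(
                QOIBound(int(row.index), float(row.value), float(row.uncertainty))
            )
        except (TypeError, ValueError) as exc:
            raise InvalidBoundError(f"{source}: malformed row {row_no}: {exc}") from exc
    return QOITable(bounds)


def load_qoi_table(source: Union[str, Path] = "default") -> QOITable:
    """Load a QOI table from a CSV file, or the embedded default.

    The CSV dialect is comma-separated with header ``index,value,uncertainty``
    and ``.`` as the decimal separator.
    """
    if isinstance(source, str) and source == "default":
        return QOITable(QOIBound(*row) for row in DEFAULT_QOI_ROWS)
    try:
        df = pd.read_csv(source)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InvalidBoundError(f"could not parse QOI table {source}: {exc}") from exc
    return _table_from_frame(df, str(source))


def load_qoi_table_str(text: str) -> QOITable:
    """Parse a QOI table from CSV text (same dialect as :func:`load_qoi_table`)."""
    return _table_from_frame(pd.read_csv(io.StringIO(text)), "<string>")


def relax_bounds(table: QOITable, half_width: float) -> QOITable:
    """Replace every half-width by ``half_width`` (values/indices unchanged).

    Used to re-examine feasibility at chemical accuracy (±1 kcal/mol)
    instead of the reported experimental uncertainty.
    """
    if not half_width > 0:
        raise InvalidBoundError(f"half_width must be > 0, got {half_width!r}")
    return QOITable(QOIBound(b.index, b.value, half_width) for b in table)
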