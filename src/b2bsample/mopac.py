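"""Text-only adapter contract for an external MOPAC-style evaluator.

The pipeline never executes an electronic-structure code; this module only
generates input decks (fixed geometry, single-point, with an external
parameter block naming all 27 adjustable values) and parses the final
heat-of-formation line from output text.  Geometries are frozen by
contract: decks carry the single-point keyword and no optimization flags.
"""

from __future__ import annotations

import re
from typing import TYPE_CHECKING, Union

if TYPE_CHECKING:
    from typing import Mapping

import numpy as np

__all__ = [
    "BUTANE_GEOMETRY",
    "MopacTemplateError",
    "MopacParseError",
    "MopacEvaluationFailed",
    "mopac_write_input",
    "mopac_parse_output",
]


class MopacTemplateError(ValueError):
    """Deck template and parameter names do not line up."""


class MopacParseError(ValueError):
    """Output text does not contain a parsable final heat of formation."""


class MopacEvaluationFailed(RuntimeError):
    """Output text carries an explicit convergence-failure marker."""


#: Approximate anti-periplanar n-butane cartesians (Angstrom), used as the
#: default frozen geometry block.
BUTANE_GEOMETRY = """\
C   0.0000   0.0000   0.0000
C   1.5300   0.0000   0.0000
C   2.0500   1.4400   0.0000
C   3.5800   1.4400   0.0000
H  -0.3900  -0.5100   0.8900
H  -0.3900  -0.5100  -0.8900
H  -0.3900   1.0200   0.0000
H   1.9200  -0.5100  -0.8900
H   1.9200  -0.5100   0.8900
H   1.6600   1.9500   0.8900
H   1.6600   1.9500  -0.8900
H   3.9700   0.4200   0.0000
H   3.9700   1.9500   0.8900
H   3.9700   1.9500  -0.8900
"""

DEFAULT_TEMPLATE = """\
PM7 1SCF EXTERNAL=PARAMS GEO-OK
 single-point heat of formation, frozen geometry
 parameter block follows the geometry

{geometry}
PARAMS
{params}
END
"""

_HOF_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/?MOL", re.IGNORECASE
)
_FAILURE_MARKERS = (
    "UNABLE TO ACHIEVE SELF-CONSISTENCE",
    "EXCESS NUMBER OF OPTIMIZATION CYCLES",
    "CALCULATION IS TERMINATED",
    "JOB FAILED",
)


def mopac_write_input(
    x: Union["Mapping[str, float]", object],
    geometry: str = BUTANE_GEOMETRY,
    template: str = DEFAULT_TEMPLATE,
) -> str:
    """Emit a single-point input deck with an external-parameter block.

    ``x`` is a :class:`~b2bsample.synthetic_model.ParameterVector` or a
    name-to-value mapping covering the full 27-name registry.  Values are
    written with ``repr`` so that :func:`parse_own_deck` recovers them
    bit-exactly.
    """
    from .synthetic_model import PARAMETER_NAMES, ParameterVector

    if isinstance(x, ParameterVector):
        values = x.as_dict()
    else:
        try:
            values = ParameterVector(x).as_dict()
        except (TypeError, ValueError) as exc:
            raise MopacTemplateError(str(exc)) from exc
    missing = [n for n in PARAMETER_NAMES if n not in values]
    if missing:
        raise MopacTemplateError(f"missing parameter names: {missing}")
    params = "\n".join(f"{name}={values[name]!r}" for name in PARAMETER_NAMES)
    for placeholder in ("{geometry}", "{params}"):
        if placeholder not in template:
            raise MopacTemplateError(f"template lacks {placeholder}")
    deck = template.format(geometry=geometry.rstrip("\n"), params=params)
    if any(flag in deck.split("\n", 1)[0] for flag in (" OPT", " EF", " TS")):
        raise MopacTemplateError("geometry must stay frozen: optimization keyword found")
    return deck


def parse_own_deck(deck: str) -> dict[str, float]:
    """Inverse of :func:`mopac_write_input`'s parameter block (bit-exact)."""
    from .synthetic_model import PARAMETER_NAMES

    lines = deck.splitlines()
    try:
        start = lines.index("PARAMS") + 1
        stop = lines.index("END", start)
    except ValueError as exc:
        raise MopacParseError("deck has no PARAMS/END block") from exc
    values: dict[str, float] = {}
    for line in lines[start:stop]:
        name, _, raw = line.partition("=")
        if not raw:
            raise MopacParseError(f"malformed parameter line: {line!r}")
        values[name.strip()] = float(raw)
    missing = [n for n in PARAMETER_NAMES if n not in values]
    extra = [n for n in values if n not in PARAMETER_NAMES]
    if missing or extra:
        raise MopacParseError(f"parameter names mismatch (missing={missing}, unknown={extra})")
    return values


def mopac_parse_output(text: str) -> float:
    """Extract the final heat of formation (kcal/mol) from output text.

    Raises :class:`MopacEvaluationFailed` on convergence-failure markers and
    :class:`MopacParseError` when no final value is present.
    """
    upper = text.upper()
    for marker in _FAILURE_MARKERS:
        if marker in upper:
            raise MopacEvaluationFailed(f"evaluation failed: {marker.lower()!r}")
    matches = _HOF_RE.findall(text)
    if not matches:
        raise MopacParseError("no final heat-of-formation line found")
    value = float(matches[-1])
    if not np.isfinite(value):
        raise MopacParseError(f"non-finite heat of formation: {value}")
    return value
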