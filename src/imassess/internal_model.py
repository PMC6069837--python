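"""Internal-model uncertainty score combining adaptation rate and JND.

The score quantifies how much a user must distrust their feedforward model
of the controller: it grows with the perception threshold (a user who
cannot feel small control-space rotations cannot calibrate the model) and
with the distance of the adaptation rate from unity (under- or
over-correction of trial errors).  The exact published scoring rule lives
in the framework this assessment derives from and is not restated here;
the default is a transparent surrogate with the same qualitative contract
— low JND plus near-unity adaptation means low uncertainty — and the rule
is pluggable through ``formula_id`` so a different rule can be dropped in
without an API change.  Printed uncertainty magnitudes from group studies
are therefore not comparable; orderings are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

__all__ = ["InternalModelEstimate", "compute_pparam", "register_formula"]

FULL_ROTATION_DEG = 90.0  # the control-space extreme used for normalization


def _default_formula(rate: float, jnd_deg: float) -> float:
    """(jnd/90)^2 * (1 + |1 - rate|): strictly increasing in jnd and in |1-rate|."""
    return (jnd_deg / FULL_ROTATION_DEG) ** 2 * (1.0 + abs(1.0 - rate))


_FORMULAS: dict[str, Callable[[float, float], float]] = {
    "normalized_jnd_sq_times_rate_error": _default_formula,
}
DEFAULT_FORMULA_ID = "normalized_jnd_sq_times_rate_error"


def register_formula(formula_id: str, fn: Callable[[float, float], float]) -> None:
    """Plug in an alternative scoring rule under a new identifier."""
    _FORMULAS[formula_id] = fn


@dataclass(frozen=True)
class InternalModelEstimate:
    p_param: float
    adaptation_rate: float
    jnd_deg: float
    formula_id: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "p_param": self.p_param,
                    "inputs": {
                        "adaptation_rate": self.adaptation_rate,
                        "jnd_deg": self.jnd_deg,
                    },
                    "formula_id": self.formula_id,
                },
                indent=2,
            )
        )


def compute_pparam(
    rate: float, jnd: float, formula_id: str = DEFAULT_FORMULA_ID
) -> InternalModelEstimate:
    """Score internal-model uncertainty from adaptation rate and JND (degrees).

    Deterministic given inputs and formula; p_param >= 0 with the default
    rule, reaching zero only in the limit of a vanishing sensory threshold
    with perfect (unity) adaptation.
    """
    if jnd <= 0:
        raise ValueError("jnd must be positive")
    if not (rate == rate and abs(rate) != float("inf")):
        raise ValueError("adaptation rate must be finite")
    fn = _FORMULAS[formula_id]
    return InternalModelEstimate(
        p_param=fn(rate, jnd),
        adaptation_rate=rate,
        jnd_deg=jnd,
        formula_id=formula_id,
    )
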