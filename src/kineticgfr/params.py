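"""Parameter model, unit canonicalisation, and clinical validity rules.

The model works internally in one consistent unit system:

* volumes in L, times in h, concentrations in mg/dL;
* clearances (kinetic GFR, volume-change rate) in L/h;
* the creatinine generation rate in mg/dL·L/h.

Clinicians quote GFR in mL/min and Gen in mg/dL·mL/min; both convert with
the single factor 1 mL/min = 0.06 L/h, applied once at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

from .errors import UnitError

#: 1 mL/min expressed in L/h.
ML_MIN_TO_L_H = 0.06

# unit label -> (canonical dimension key, multiplicative factor)
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    "mg/dL": ("concentration", 1.0),
    "mL/min": ("clearance", ML_MIN_TO_L_H),
    "L/h": ("clearance", 1.0),
    "mg/dL·mL/min": ("generation", ML_MIN_TO_L_H),
    "mg/dL*mL/min": ("generation", ML_MIN_TO_L_H),
    "mg/dL·L/h": ("generation", 1.0),
    "mg/dL*L/h": ("generation", 1.0),
    "L": ("volume", 1.0),
    "h": ("time", 1.0),
    "min": ("time", 1.0 / 60.0),
}

_FIELD_DIMENSION = {
    "cr0": "concentration",
    "gen": "generation",
    "gfr_k": "clearance",
    "v0": "volume",
    "dv_dt": "clearance",
}

#: Soft sanity ceiling for a positive volume-change rate, L/h.  The model
#: itself imposes no upper bound; exceeding this only raises a warning.
DV_DT_SANITY_BOUND = 10.0

STRICT = "strict-clinical"
EXTENDED = "extended-math"


@dataclass(frozen=True)
class KineticParams:
    """One clinical interval's parameter set, in canonical units.

    Attributes
    ----------
    cr0 : float
        Initial serum creatinine at the interval's time zero, mg/dL.
    gen : float
        Creatinine generation rate, mg/dL·L/h.
    gfr_k : float
        Kinetic GFR (renal creatinine clearance), L/h.
    v0 : float
        Initial volume of distribution (total body water), L.
    dv_dt : float
        Constant net rate of change of the volume of distribution, L/h.
    """

    cr0: float
    gen: float
    gfr_k: float
    v0: float
    dv_dt: float

    @classmethod
    def from_clinical(
        cls,
        cr0: float,
        gen_ml_min: float,
        gfr_k_ml_min: float,
        v0: float,
        dv_dt_l_h: float,
    ) -> "KineticParams":
        """Build from the units a clinician would quote (GFR and Gen per
        mL/min, volume rate already in L/h)."""
        return cls(
            cr0=float(cr0),
            gen=float(gen_ml_min) * ML_MIN_TO_L_H,
            gfr_k=float(gfr_k_ml_min) * ML_MIN_TO_L_H,
            v0=float(v0),
            dv_dt=float(dv_dt_l_h),
        )

    def with_gfr(self, gfr_k: float) -> "KineticParams":
        """Copy with a different canonical (L/h) kinetic GFR."""
        return replace(self, gfr_k=gfr_k)

    @property
    def gfr_k_ml_min(self) -> float:
        return self.gfr_k / ML_MIN_TO_L_H


def convert(value: float, unit: str) -> tuple[float, str]:
    """Convert one quantity to canonical units.

    Returns the canonical value and the dimension key it belongs to.
    """
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r}")
    try:
        dim, factor = _UNIT_TABLE[unit]
    except KeyError:
        raise UnitError(
            f"unknown unit {unit!r}; supported: {sorted(_UNIT_TABLE)}"
        ) from None
    return value * factor, dim


def to_canonical(raw: Mapping[str, object]) -> KineticParams:
    """Canonicalise a raw parameter bundle with declared units.

    ``raw`` maps each field name (cr0, gen, gfr_k, v0, dv_dt) to either a
    ``{"value": x, "unit": u}`` mapping or a ``(value, unit)`` pair, the
    shape used by JSON config files.  Idempotent on already-canonical
    input (canonical unit labels convert with factor 1).
    """
    out: dict[str, float] = {}
    for name, dim in _FIELD_DIMENSION.items():
        if name not in raw:
            raise ValueError(f"missing parameter {name!r}")
        entry = raw[name]
        if isinstance(entry, Mapping):
            value, unit = entry["value"], entry["unit"]
        else:
            value, unit = entry  # type: ignore[misc]
        canon, got_dim = convert(value, str(unit))
        if got_dim != dim:
            raise UnitError(
                f"{name}: unit {unit!r} has dimension {got_dim}, "
                f"expected {dim}"
            )
        out[name] = canon
    return KineticParams(**out)


def to_clinical(params: KineticParams) -> dict[str, dict[str, float | str]]:
    """Inverse of :func:`to_canonical`, back to clinician-facing units."""
    return {
        "cr0": {"value": params.cr0, "unit": "mg/dL"},
        "gen": {"value": params.gen / ML_MIN_TO_L_H, "unit": "mg/dL·mL/min"},
        "gfr_k": {"value": params.gfr_k / ML_MIN_TO_L_H, "unit": "mL/min"},
        "v0": {"value": params.v0, "unit": "L"},
        "dv_dt": {"value": params.dv_dt, "unit": "L/h"},
    }


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking the clinical validity rules A-E."""

    valid: bool
    violations: tuple[tuple[str, str], ...]
    warnings: tuple[str, ...] = ()
    mode: str = STRICT

    def __post_init__(self) -> None:
        assert self.valid == (len(self.violations) == 0)


def validate(
    params: KineticParams,
    horizon: float,
    mode: str = STRICT,
    dv_dt_sanity_bound: float = DV_DT_SANITY_BOUND,
) -> ValidationReport:
    """Check the model's validity rules over a time horizon.

    The rules, each checked independently so the report lists every
    violation:

    A. creatinine positive: ``cr0 > 0``;
    B. volume positive: ``v0 > 0``;
    C. kinetic GFR non-negative (strict-clinical mode only — the
       mathematics remains meaningful for negative GFR and
       ``extended-math`` mode skips this rule);
    D. generation rate positive: ``gen > 0``;
    E. volume cannot be fully depleted within the horizon:
       ``v0 + dv_dt * horizon > 0``.

    A very large positive ``dv_dt`` produces only a warning: the model
    places no upper bound on volume gain.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if mode not in (STRICT, EXTENDED):
        raise ValueError(f"unknown validation mode {mode!r}")

    violations: list[tuple[str, str]] = []
    warnings: list[str] = []

    if not params.cr0 > 0:
        violations.append(("A", f"initial creatinine must be positive, got {params.cr0}"))
    if not params.v0 > 0:
        violations.append(("B", f"initial volume must be positive, got {params.v0} L"))
    if mode == STRICT and params.gfr_k < 0:
        violations.append(
            ("C", f"kinetic GFR must be non-negative in {STRICT} mode, "
                  f"got {params.gfr_k} L/h")
        )
    if not params.gen > 0:
        violations.append(("D", f"generation rate must be positive, got {params.gen}"))
    end_volume = params.v0 + params.dv_dt * horizon
    if not end_volume > 0:
        violations.append(
            ("E", f"volume would be depleted within {horizon} h: "
                  f"V0 + dV/dt·t = {end_volume} L ≤ 0 "
                  f"(requires dV/dt > {-params.v0 / horizon if horizon else -math.inf} L/h)")
        )
    if params.dv_dt > dv_dt_sanity_bound:
        warnings.append(
            f"dV/dt = {params.dv_dt} L/h exceeds the sanity bound "
            f"{dv_dt_sanity_bound} L/h; allowed but clinically implausible"
        )

    return ValidationReport(
        valid=not violations,
        violations=tuple(violations),
        warnings=tuple(warnings),
        mode=mode,
    )
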