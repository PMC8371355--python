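"""Analytic sensitivities of serum creatinine to the kinetic parameters.

The central quantity is the partial derivative of creatinine with
respect to kinetic GFR at fixed time,

    ∂[Cr]_t/∂GFR_K = a′·b + a·b′,

with a = 1 − (V0/V_t)^(1+g/d) the time-evolution factor and
b = Gen/(g+d) − Cr0 the concentration spread (g = GFR_K, d = dV/dt).
Written out, the derivative is 0/0 at three parameter loci; each has a
closed-form limit and the dispatcher selects the branch:

* ``limit-dv0``            d = 0 (the common fixed-volume case);
* ``limit-gfr-eq-neg-dv``  g = −d, d ≠ 0;
* ``limit-both-zero``      g = d = 0.

On the whole valid parameter region the derivative is strictly negative
for t > 0 — creatinine and kinetic GFR can only move in opposite
directions at fixed time.  :func:`sign_scan` verifies that property
numerically over seeded random draws.

The volume-rate sensitivity ∂[Cr]_t/∂(dV/dt) is also provided; it has no
sign constraint (volume loss concentrates, volume gain dilutes, but the
steady-state target moves too).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import RATE_EPS, creatinine_at, volume_at
from .errors import OracleError, UnsupportedBranchError
from .params import ML_MIN_TO_L_H, KineticParams

BRANCH_GENERAL = "general"
BRANCH_DV0 = "limit-dv0"
BRANCH_GFR_NEG_DV = "limit-gfr-eq-neg-dv"
BRANCH_BOTH_ZERO = "limit-both-zero"


@dataclass(frozen=True)
class SensitivityResult:
    """A derivative value plus the formula branch that produced it.

    ``value`` is reported in the clinical unit mg/dL per mL/min;
    ``value_per_l_h`` is the same slope per L/h of GFR (÷ 0.06).
    """

    value: float
    value_per_l_h: float
    branch: str
    at: tuple[KineticParams, float]


def _result(internal: float, branch: str, params: KineticParams, t: float) -> SensitivityResult:
    return SensitivityResult(
        value=internal * ML_MIN_TO_L_H,
        value_per_l_h=internal,
        branch=branch,
        at=(params, t),
    )


def _general(params: KineticParams, t: float) -> float:
    # log1p/expm1 and the Sterbenz-exact exponent (g+d)/d keep the two
    # mutually cancelling product-rule terms accurate arbitrarily close
    # to the singular loci (they individually blow up like 1/(g+d)).
    g, d = params.gfr_k, params.dv_dt
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    volume_at(params, t)  # domain check (rules B/E)
    log_ratio = -math.log1p(d * t / v0)  # ln(V0/Vt)
    s = g + d
    power = math.exp((s / d) * log_ratio)
    a_prime = -power * log_ratio / d
    b = gen / s - cr0
    a = -math.expm1((s / d) * log_ratio)
    b_prime = -gen / s**2
    return a_prime * b + a * b_prime


def _limit_dv0(params: KineticParams, t: float) -> float:
    g = params.gfr_k
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    e = math.exp(-g * t / v0)
    return e * (t / v0) * (gen / g - cr0) - (1.0 - e) * gen / g**2


def _limit_gfr_eq_neg_dv(params: KineticParams, t: float) -> float:
    d = params.dv_dt
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    volume_at(params, t)  # domain check
    log_ratio = -math.log1p(d * t / v0)  # ln(V0/Vt)
    return -(log_ratio / d) * (gen * log_ratio / (2.0 * d) - cr0)


def _limit_both_zero(params: KineticParams, t: float) -> float:
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    return -(t / v0) * (gen * t / (2.0 * v0) + cr0)


def dcr_dgfr(params: KineticParams, t: float) -> SensitivityResult:
    """∂[Cr]_t/∂GFR_K at fixed time, with automatic branch dispatch.

    Reported in mg/dL per mL/min.  Zero exactly at t = 0; strictly
    negative for every clinically valid parameter set with t > 0.
    """
    g, d = params.gfr_k, params.dv_dt
    near_d0 = abs(d) < RATE_EPS
    if near_d0 and abs(g) < RATE_EPS:
        return _result(_limit_both_zero(params, t), BRANCH_BOTH_ZERO, params, t)
    if near_d0:
        return dcr_dgfr_limit_dv0(params, t)
    if abs(g + d) < RATE_EPS:
        return dcr_dgfr_limit_gfr_eq_neg_dv(params, t)
    return _result(_general(params, t), BRANCH_GENERAL, params, t)


def dcr_dgfr_general(params: KineticParams, t: float) -> SensitivityResult:
    """The general product-rule formula, with no branch dispatch.

    Useful for checking continuity against the limit branches at small
    parameter offsets; numerically unstable at the singular loci
    themselves (dV/dt = 0 or GFR_K + dV/dt = 0).
    """
    return _result(_general(params, t), BRANCH_GENERAL, params, t)


def dcr_dgfr_limit_dv0(params: KineticParams, t: float) -> SensitivityResult:
    """The dV/dt → 0 limit of ∂[Cr]_t/∂GFR_K:

    exp(−g·t/V0)·(t/V0)·(Gen/g − Cr0) − (1 − exp(−g·t/V0))·Gen/g².

    The g = 0 case is routed to the both-zero branch, never evaluated
    here (the expression above is 0/0 there).
    """
    if abs(params.gfr_k) < RATE_EPS:
        return _result(_limit_both_zero(params, t), BRANCH_BOTH_ZERO, params, t)
    return _result(_limit_dv0(params, t), BRANCH_DV0, params, t)


def dcr_dgfr_limit_gfr_eq_neg_dv(params: KineticParams, t: float) -> SensitivityResult:
    """The GFR_K → −dV/dt limit of ∂[Cr]_t/∂GFR_K (dV/dt ≠ 0):

    −(1/d)·ln(V0/V_t) · ( Gen/(2d)·ln(V0/V_t) − Cr0 ).

    Clinically reachable when dV/dt < 0 (GFR_K = |dV/dt|); with
    dV/dt > 0 it forces GFR_K < 0 and belongs to extended-math mode.
    The dV/dt = 0 case is routed to the both-zero branch.
    """
    if abs(params.dv_dt) < RATE_EPS:
        return _result(_limit_both_zero(params, t), BRANCH_BOTH_ZERO, params, t)
    return _result(_limit_gfr_eq_neg_dv(params, t), BRANCH_GFR_NEG_DV, params, t)


def dcr_dgfr_limit_both_zero(params: KineticParams, t: float) -> SensitivityResult:
    """The GFR_K, dV/dt → 0 limit of ∂[Cr]_t/∂GFR_K:

    −(t/V0)·( Gen·t/(2·V0) + Cr0 ),

    which is ≤ 0 always and 0 only at t = 0.
    """
    return _result(_limit_both_zero(params, t), BRANCH_BOTH_ZERO, params, t)


def dcr_dvolrate(params: KineticParams, t: float) -> float:
    """∂[Cr]_t/∂(dV/dt) at fixed time, mg/dL per (L/h).

    Only the general branch has a published closed form; near the
    removable singularities (dV/dt ≈ 0 or GFR_K + dV/dt ≈ 0) this raises
    :class:`UnsupportedBranchError` rather than evaluating an unverified
    limit.  The sign is not constrained.
    """
    g, d = params.gfr_k, params.dv_dt
    if abs(d) < RATE_EPS or abs(g + d) < RATE_EPS:
        raise UnsupportedBranchError(
            "no closed-form limit branch for d[Cr]/d(dV/dt) near "
            "dV/dt = 0 or GFR_K + dV/dt = 0"
        )
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    vt = volume_at(params, t)
    log_ratio = -math.log1p(d * t / v0)  # ln(V0/Vt)
    s = g + d
    power = math.exp((s / d) * log_ratio)
    term1 = power * ((g / d**2) * log_ratio + (s / d) * t / vt)
    b = gen / s - cr0
    term2 = -math.expm1((s / d) * log_ratio) * (-gen / s**2)
    return term1 * b + term2


def finite_difference(
    target: str,
    params: KineticParams,
    t: float,
    h: float = 1e-4,
) -> float:
    """Central finite difference of [Cr]_t over one parameter, per L/h.

    ``target`` is ``"gfr_k"`` or ``"dv_dt"``; ``h`` is the step in L/h.
    If a perturbed parameter set is invalid (volume depleted before t),
    the step is shrunk once by 100x before giving up.
    """
    if target not in ("gfr_k", "dv_dt"):
        raise ValueError(f"unsupported finite-difference target {target!r}")
    for step in (h, h / 100.0):
        lo = replace(params, **{target: getattr(params, target) - step})
        hi = replace(params, **{target: getattr(params, target) + step})
        try:
            return (creatinine_at(hi, t) - creatinine_at(lo, t)) / (2.0 * step)
        except Exception:
            continue
    raise OracleError(
        f"finite difference on {target} failed at t={t} even after "
        "shrinking the step"
    )


#: Default sampling ranges for the sign scan, in the units clinicians
#: quote (GFR and Gen per mL/min; volumes L; times h; dV/dt L/h).
DEFAULT_SCAN_RANGES: dict[str, tuple[float, float]] = {
    "cr0": (0.2, 15.0),
    "gen_ml_min": (20.0, 150.0),
    "gfr_k_ml_min": (0.0, 120.0),
    "v0": (20.0, 60.0),
    "t": (0.0, 72.0),        # lower bound exclusive: derivative is 0 at t=0
    "dv_dt": (None, 0.5),    # lower bound is -v0/t per draw (rule E)
}


@dataclass(frozen=True)
class SignScanReport:
    """Result of a randomized sign scan of ∂[Cr]_t/∂GFR_K.

    ``n_nonnegative == 0`` is the numerical statement that the
    derivative is negative everywhere on the valid region with t > 0.
    """

    n_samples: int
    n_nonnegative: int
    worst_case: tuple[KineticParams, float, float]  # (params, t, value)
    ranges: dict
    seed: int


def sign_scan(
    n: int = 100_000,
    seed: int = 1,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
) -> SignScanReport:
    """Draw ``n`` valid parameter sets and count non-negative derivatives.

    Each draw samples cr0, Gen, GFR_K, V0 and t uniformly from its
    range, then samples dV/dt uniformly between just above the rule-E
    depletion bound −V0/t and the range's upper limit.  All dispatch
    branches of :func:`dcr_dgfr` are reachable.  The worst case (largest
    derivative) is reported for inspection.
    """
    spec = dict(DEFAULT_SCAN_RANGES)
    if ranges:
        spec.update(ranges)
    rng = np.random.default_rng(seed)

    cr0 = rng.uniform(*spec["cr0"], size=n)
    gen = rng.uniform(*spec["gen_ml_min"], size=n) * ML_MIN_TO_L_H
    gfr = rng.uniform(*spec["gfr_k_ml_min"], size=n) * ML_MIN_TO_L_H
    v0 = rng.uniform(*spec["v0"], size=n)
    t_lo, t_hi = spec["t"]
    t = t_lo + (t_hi - t_lo) * (1.0 - rng.uniform(size=n))  # (t_lo, t_hi]
    dv_lo, dv_hi = spec["dv_dt"]
    lower = (-v0 / t) * (1.0 - 1e-6) if dv_lo is None else np.full(n, dv_lo)
    dv = lower + (dv_hi - lower) * rng.uniform(size=n)

    n_nonneg = 0
    worst_val = -np.inf
    worst: tuple[KineticParams, float, float] | None = None
    for i in range(n):
        p = KineticParams(cr0=cr0[i], gen=gen[i], gfr_k=gfr[i],
                          v0=v0[i], dv_dt=dv[i])
        val = dcr_dgfr(p, t[i]).value
        if val >= 0:
            n_nonneg += 1
        if val > worst_val:
            worst_val = val
            worst = (p, float(t[i]), float(val))
    assert worst is not None
    return SignScanReport(
        n_samples=n,
        n_nonnegative=n_nonneg,
        worst_case=worst,
        ranges=spec,
        seed=seed,
    )
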