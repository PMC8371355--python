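"""Forward model: closed-form creatinine kinetics with changing volume.

The serum creatinine obeys the mass balance

    d/dt ( [Cr]_t · V_t ) = Gen − GFR_K · [Cr]_t,      V_t = V0 + (dV/dt)·t,

whose closed-form solution, for constant GFR_K and dV/dt, is

    [Cr]_t = Cr0 + [ 1 − (V0/V_t)^(1 + GFR_K/(dV/dt)) ]
                   · ( Gen/(GFR_K + dV/dt) − Cr0 ).

The bracketed "time evolution" factor carries the concentration from its
initial value toward the steady state Gen/(GFR_K + dV/dt).  Two parameter
loci make the written formula 0/0 and are evaluated by their limits:

* dV/dt → 0: the textbook fixed-volume one-compartment solution
  ``Cr0·exp(−g·t/V0) + (Gen/g)·(1 − exp(−g·t/V0))`` (and its g → 0 limit,
  linear accumulation ``Cr0 + Gen·t/V0``);
* GFR_K + dV/dt → 0 with dV/dt ≠ 0: ``Cr0 + (Gen/(dV/dt))·ln(V_t/V0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, NoSteadyStateError, OracleError
from .params import KineticParams

#: Below this (L/h) a denominator rate is treated as zero and the matching
#: limit branch is used.  Continuity tests pin the crossover error < 1e-6.
RATE_EPS = 1e-8


@dataclass(frozen=True)
class Trajectory:
    """Time grid with creatinine concentrations and distribution volumes."""

    times: np.ndarray      # h, from interval start
    creatinine: np.ndarray  # mg/dL
    volume: np.ndarray     # L

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.creatinine) == len(self.volume)):
            raise ValueError("trajectory arrays must have equal length")


def volume_at(params: KineticParams, t: float) -> float:
    """Volume of distribution V_t = V0 + (dV/dt)·t, in L.

    Raises :class:`DomainError` if the volume is not positive (rules B/E).
    """
    v = params.v0 + params.dv_dt * t
    if not v > 0:
        raise DomainError(
            f"volume of distribution non-positive at t={t} h: {v} L "
            "(violates rules B/E)"
        )
    return v


def steady_state_cr(params: KineticParams) -> float:
    """Steady-state creatinine Gen / (GFR_K + dV/dt), mg/dL.

    Requires positive total clearance; otherwise creatinine has no finite
    asymptote and :class:`NoSteadyStateError` signals the limit regime.
    """
    total = params.gfr_k + params.dv_dt
    if not total > 0:
        raise NoSteadyStateError(
            f"GFR_K + dV/dt = {total} L/h ≤ 0: no finite steady state"
        )
    return params.gen / total


def creatinine_at(params: KineticParams, t: float) -> float:
    """Serum creatinine at time ``t`` hours, mg/dL (closed form).

    Continuous in all parameters: near the removable singularities the
    appropriate limit branch is evaluated instead of the general formula.
    The power term is computed in log space so large exponents
    (1 + GFR_K/(dV/dt) can exceed 20 in routine scenarios) do not overflow.
    """
    if t < 0:
        raise DomainError("time must be non-negative")
    if t == 0:
        return params.cr0
    g, d = params.gfr_k, params.dv_dt
    cr0, gen, v0 = params.cr0, params.gen, params.v0
    vt = volume_at(params, t)

    if abs(d) < RATE_EPS:
        if abs(g) < RATE_EPS:
            # no clearance at all: linear accumulation
            return cr0 + gen * t / v0
        e = np.exp(-g * t / v0)
        return cr0 * e + (gen / g) * (1.0 - e)

    if abs(g + d) < RATE_EPS:
        # total clearance vanishes: no steady state, logarithmic growth
        return cr0 + (gen / d) * np.log1p(d * t / v0)

    # log1p/expm1 with the exponent (g+d)/d keep the evolution factor
    # accurate near the singular loci and overflow-free at large exponents
    s = g + d
    log_ratio = -np.log1p(d * t / v0)  # ln(V0/Vt)
    evolution = -np.expm1((s / d) * log_ratio)
    return cr0 + evolution * (gen / s - cr0)


def ode_rhs(params: KineticParams, t: float, cr: float) -> float:
    """d[Cr]/dt in mg/dL per h, from the mass balance rearranged as

    d[Cr]/dt = (Gen − GFR_K·[Cr] − [Cr]·dV/dt) / V_t,

    so that d([Cr]·V)/dt = Gen − GFR_K·[Cr] holds identically.
    """
    vt = volume_at(params, t)
    return (params.gen - params.gfr_k * cr - cr * params.dv_dt) / vt


def simulate(params: KineticParams, times: np.ndarray) -> Trajectory:
    """Closed-form trajectory over a sorted time grid starting at 0."""
    times = np.asarray(times, dtype=float)
    _check_grid(times)
    cr = np.array([creatinine_at(params, t) for t in times])
    vol = np.array([volume_at(params, t) for t in times])
    return Trajectory(times=times, creatinine=cr, volume=vol)


def simulate_numeric(
    params: KineticParams,
    times: np.ndarray,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> Trajectory:
    """Trajectory by adaptive high-order integration of the mass-balance
    ODE; the independent numerical oracle for the closed form.

    Tolerances are tight because values at requested times come from the
    integrator's dense-output interpolant, which is a little less
    accurate than the steps themselves.
    """
    times = np.asarray(times, dtype=float)
    _check_grid(times)
    sol = solve_ivp(
        lambda t, y: [ode_rhs(params, t, y[0])],
        (times[0], times[-1]) if times[-1] > 0 else (0.0, 1e-12),
        [params.cr0],
        t_eval=times,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise OracleError(f"ODE integration failed: {sol.message}")
    vol = np.array([volume_at(params, t) for t in times])
    return Trajectory(times=times, creatinine=sol.y[0], volume=vol)


def _check_grid(times: np.ndarray) -> None:
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if times[0] != 0:
        raise ValueError("time grid must start at 0 (interval start)")
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be sorted")
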