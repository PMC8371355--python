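"""Estimate kinetic GFR from serial creatinines, and the CKD reciprocal.

Given two creatinine measurements bracketing an interval of length dt,
the forward model [Cr]_dt(GFR_K) is strictly decreasing in GFR_K (the
derivative is negative everywhere on the valid region), so the equation
[Cr]_dt(GFR_K) = observed has at most one root and bracketed root
finding recovers it safely.  A measurement outside the attainable band
[[Cr]_dt(G_max), [Cr]_dt(0)] is flagged, never clamped.

For chronic kidney disease the steady-state picture applies: creatinine
is the reciprocal Gen/GFR, with tangent slope −Gen/GFR².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import creatinine_at
from .errors import DomainError
from .params import ML_MIN_TO_L_H, KineticParams

#: Default root-search ceiling for kinetic GFR, mL/min (physiologic GFR
#: with a wide margin; monotonicity makes the bracket safe).
G_MAX_ML_MIN = 300.0

#: Bisection tolerance on the recovered GFR, mL/min.
GFR_TOL_ML_MIN = 1e-8


@dataclass(frozen=True)
class MeasurementSeries:
    """Timestamped serial creatinine observations.

    ``times`` are hours from the series start, strictly increasing;
    ``fluid_balance`` (optional) is the net fluid gain in L accrued over
    each inter-measurement interval, so it has one fewer entry than
    ``times``.
    """

    times: np.ndarray
    creatinine: np.ndarray
    fluid_balance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "creatinine",
                           np.asarray(self.creatinine, dtype=float))
        if len(self.times) != len(self.creatinine):
            raise ValueError("times and creatinine must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.creatinine <= 0):
            raise ValueError("creatinine values must be positive")
        if self.fluid_balance is not None:
            fb = np.asarray(self.fluid_balance, dtype=float)
            if len(fb) != len(self.times) - 1:
                raise ValueError(
                    "fluid_balance needs one entry per inter-measurement "
                    f"interval ({len(self.times) - 1}), got {len(fb)}"
                )
            object.__setattr__(self, "fluid_balance", fb)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "MeasurementSeries":
        """Read ``time_h, creatinine_mg_dl[, net_fluid_l]`` columns.

        ``net_fluid_l`` on each row is the balance accrued since the
        previous row; the first row's entry is ignored.
        """
        df = pd.read_csv(path)
        fb = None
        if "net_fluid_l" in df.columns:
            fb = df["net_fluid_l"].to_numpy(dtype=float)[1:]
            fb = np.nan_to_num(fb, nan=0.0)
        return cls(
            times=df["time_h"].to_numpy(dtype=float),
            creatinine=df["creatinine_mg_dl"].to_numpy(dtype=float),
            fluid_balance=fb,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            {"time_h": self.times, "creatinine_mg_dl": self.creatinine}
        )
        if self.fluid_balance is not None:
            df["net_fluid_l"] = np.concatenate([[np.nan], self.fluid_balance])
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class IntervalEstimate:
    """A per-interval inverted kinetic GFR with diagnostics.

    ``gfr_k_hat`` is in mL/min.  When ``converged`` is False the
    observed creatinine was outside the band attainable by any GFR in
    the search bracket and ``note`` says which side; the residual is the
    distance to the nearest attainable value.
    """

    interval: tuple[float, float]
    gfr_k_hat: float
    converged: bool
    residual: float
    note: str = ""


def invert_gfr(
    cr0: float,
    crt: float,
    dt: float,
    v0: float,
    dv_dt: float,
    gen: float,
    g_max_ml_min: float = G_MAX_ML_MIN,
    t_start: float = 0.0,
) -> IntervalEstimate:
    """Solve the forward model for the kinetic GFR over one interval.

    Parameters are canonical (volumes L, rates L/h, Gen mg/dL·L/h);
    the estimate is reported in mL/min.  ``dt`` must be positive.
    """
    if dt <= 0:
        raise ValueError(f"interval length must be positive, got {dt} h")
    g_max = g_max_ml_min * ML_MIN_TO_L_H

    def forward(g: float) -> float:
        p = KineticParams(cr0=cr0, gen=gen, gfr_k=g, v0=v0, dv_dt=dv_dt)
        return creatinine_at(p, dt)

    cr_hi = forward(0.0)      # no clearance: highest attainable
    cr_lo = forward(g_max)    # max clearance: lowest attainable
    interval = (t_start, t_start + dt)
    if crt > cr_hi:
        return IntervalEstimate(
            interval=interval, gfr_k_hat=float("nan"), converged=False,
            residual=crt - cr_hi,
            note=f"observed {crt} mg/dL above attainable maximum {cr_hi:.6g} "
                 "(even GFR_K = 0 cannot explain it)",
        )
    if crt < cr_lo:
        return IntervalEstimate(
            interval=interval, gfr_k_hat=float("nan"), converged=False,
            residual=cr_lo - crt,
            note=f"observed {crt} mg/dL below attainable minimum {cr_lo:.6g} "
                 f"at the bracket ceiling {g_max_ml_min} mL/min",
        )
    root = brentq(
        lambda g: forward(g) - crt,
        0.0,
        g_max,
        xtol=GFR_TOL_ML_MIN * ML_MIN_TO_L_H,
        rtol=8.9e-16,
    )
    residual = abs(forward(root) - crt)
    return IntervalEstimate(
        interval=interval,
        gfr_k_hat=root / ML_MIN_TO_L_H,
        converged=True,
        residual=residual,
    )


def invert_series(
    series: MeasurementSeries,
    v0: float,
    gen: float,
    g_max_ml_min: float = G_MAX_ML_MIN,
) -> list[IntervalEstimate]:
    """One GFR estimate per consecutive measurement pair.

    Each interval's dV/dt is its net fluid balance divided by its
    length (0 when no balance is recorded), and the next interval's V0
    is the previous interval's end volume.  A non-attainable interval is
    flagged in place; the remaining intervals are still estimated.
    """
    if len(series.times) < 2:
        raise ValueError("need at least two measurements")
    estimates: list[IntervalEstimate] = []
    v = float(v0)
    for i in range(len(series.times) - 1):
        dt = series.times[i + 1] - series.times[i]
        balance = (
            float(series.fluid_balance[i])
            if series.fluid_balance is not None else 0.0
        )
        dv_dt = balance / dt
        estimates.append(
            invert_gfr(
                cr0=float(series.creatinine[i]),
                crt=float(series.creatinine[i + 1]),
                dt=float(dt),
                v0=v,
                dv_dt=dv_dt,
                gen=gen,
                g_max_ml_min=g_max_ml_min,
                t_start=float(series.times[i]),
            )
        )
        v += balance
    return estimates


def estimates_to_frame(estimates: Sequence[IntervalEstimate]) -> pd.DataFrame:
    """Tabulate interval estimates for CSV export."""
    return pd.DataFrame(
        {
            "interval_start_h": [e.interval[0] for e in estimates],
            "interval_end_h": [e.interval[1] for e in estimates],
            "gfr_k_ml_min": [e.gfr_k_hat for e in estimates],
            "converged": [e.converged for e in estimates],
            "residual": [e.residual for e in estimates],
            "note": [e.note for e in estimates],
        }
    )


def ckd_cr(gen: float, gfr: float) -> float:
    """Steady-state CKD creatinine: Gen/GFR (Gen in mg/dL·mL/min, GFR in
    mL/min, result mg/dL)."""
    if gfr <= 0:
        raise DomainError(f"GFR must be positive, got {gfr}")
    return gen / gfr


def ckd_slope(gen: float, gfr: float) -> float:
    """Tangent slope of the CKD reciprocal curve: −Gen/GFR², in mg/dL
    per mL/min.  Always negative for valid input."""
    if gfr <= 0:
        raise DomainError(f"GFR must be positive, got {gfr}")
    return -gen / gfr**2
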