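"""Regenerate the model's four illustrative figures.

1. Creatinine at 24 h versus kinetic GFR for the acute-injury vignette,
   with computed tangents at GFR_K = 10 and −90 mL/min (the latter is
   extended-math territory and shows the formula remains smooth there).
2. The sensitivity ∂Cr/∂GFR_K versus GFR_K for the vignette parameters
   and for an extreme-but-allowed parameter set; both stay below zero.
3. The chronic-disease reciprocal Cr = Gen/GFR with its tangents at the
   low and high ends of the creatinine scale.
4. Low- versus high-initial-creatinine acute curves with the worked
   tangent slopes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import creatinine_at
from .inversion import ckd_cr, ckd_slope
from .params import ML_MIN_TO_L_H, KineticParams
from .sensitivity import dcr_dgfr


def _cr_vs_gfr(base: KineticParams, gfr_ml_min: np.ndarray, t: float) -> np.ndarray:
    return np.array([
        creatinine_at(base.with_gfr(g * ML_MIN_TO_L_H), t) for g in gfr_ml_min
    ])


def _tangent(base: KineticParams, g0_ml_min: float, t: float,
             gfr_ml_min: np.ndarray) -> np.ndarray:
    slope = dcr_dgfr(base.with_gfr(g0_ml_min * ML_MIN_TO_L_H), t).value
    y0 = creatinine_at(base.with_gfr(g0_ml_min * ML_MIN_TO_L_H), t)
    return y0 + slope * (gfr_ml_min - g0_ml_min)


def regenerate_figures(out_dir: Union[str, Path]) -> dict[str, Path]:
    """Render the four figures as PNGs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = 24.0
    vignette = KineticParams.from_clinical(
        cr0=1.0, gen_ml_min=90.0, gfr_k_ml_min=10.0, v0=42.0, dv_dt_l_h=0.25
    )
    paths: dict[str, Path] = {}

    # Figure 1: Cr vs GFR_K with tangents at 10 and -90 mL/min
    g = np.linspace(-120.0, 150.0, 400)
    fig, ax = plt.subplots()
    ax.plot(g, _cr_vs_gfr(vignette, g, t), "r-", label="[Cr] at 24 h")
    for g0, style in ((10.0, "k--"), (-90.0, "m--")):
        window = np.linspace(g0 - 30, g0 + 30, 50)
        ax.plot(window, _tangent(vignette, g0, t, window), style,
                label=f"tangent at GFR_K={g0:g}")
        ax.plot([g0], [_cr_vs_gfr(vignette, np.array([g0]), t)[0]], "o")
    ax.set_xlabel("kinetic GFR (mL/min)")
    ax.set_ylabel("[Cr] at 24 h (mg/dL)")
    ax.legend()
    paths["cr_vs_gfr_tangents"] = out / "fig1_cr_vs_gfr_tangents.png"
    fig.savefig(paths["cr_vs_gfr_tangents"], dpi=120)
    plt.close(fig)

    # Figure 2: derivative vs GFR_K for vignette and extreme parameters
    extreme = KineticParams.from_clinical(
        cr0=9.0, gen_ml_min=40.0, gfr_k_ml_min=10.0, v0=30.0, dv_dt_l_h=-0.25
    )
    g = np.linspace(0.0, 120.0, 400)
    fig, ax = plt.subplots()
    for base, color, label in (
        (vignette, "r", "vignette parameters"),
        (extreme, "b", "extreme parameters"),
    ):
        deriv = [dcr_dgfr(base.with_gfr(x * ML_MIN_TO_L_H), t).value for x in g]
        ax.plot(g, deriv, color=color, label=label)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("kinetic GFR (mL/min)")
    ax.set_ylabel("d[Cr]/dGFR_K (mg/dL per mL/min)")
    ax.legend()
    paths["derivative_vs_gfr"] = out / "fig2_derivative_vs_gfr.png"
    fig.savefig(paths["derivative_vs_gfr"], dpi=120)
    plt.close(fig)

    # Figure 3: CKD reciprocal with tangents at GFR 90 and 10
    g = np.linspace(5.0, 120.0, 400)
    fig, ax = plt.subplots()
    ax.plot(g, [ckd_cr(90.0, x) for x in g], "r-", label="Cr = Gen/GFR")
    for g0, style in ((90.0, "g--"), (10.0, "b--")):
        window = np.linspace(max(g0 - 25, 1.0), g0 + 25, 50)
        tang = ckd_cr(90.0, g0) + ckd_slope(90.0, g0) * (window - g0)
        ax.plot(window, tang, style, label=f"tangent at GFR={g0:g}")
        ax.plot([g0], [ckd_cr(90.0, g0)], "o")
    ax.set_xlabel("GFR (mL/min)")
    ax.set_ylabel("steady-state [Cr] (mg/dL)")
    ax.legend()
    paths["ckd_reciprocal"] = out / "fig3_ckd_reciprocal.png"
    fig.savefig(paths["ckd_reciprocal"], dpi=120)
    plt.close(fig)

    # Figure 4: low vs high Cr0 acute curves with worked tangents
    low = KineticParams.from_clinical(1.0, 90.0, 90.0, 42.0, 0.25)
    high = KineticParams.from_clinical(9.0, 90.0, 10.0, 42.0, 0.25)
    g = np.linspace(1.0, 120.0, 400)
    fig, ax = plt.subplots()
    for base, g0, color, style in (
        (low, 90.0, "b", "g--"),
        (high, 10.0, "r", "k--"),
    ):
        ax.plot(g, _cr_vs_gfr(base, g, t), color=color,
                label=f"Cr0 = {base.cr0:g} mg/dL")
        window = np.linspace(max(g0 - 30, 1.0), g0 + 30, 50)
        ax.plot(window, _tangent(base, g0, t, window), style)
        ax.plot([g0], [_cr_vs_gfr(base, np.array([g0]), t)[0]], "o")
    ax.set_xlabel("kinetic GFR (mL/min)")
    ax.set_ylabel("[Cr] at 24 h (mg/dL)")
    ax.legend()
    paths["aki_low_vs_high_cr0"] = out / "fig4_aki_low_vs_high_cr0.png"
    fig.savefig(paths["aki_low_vs_high_cr0"], dpi=120)
    plt.close(fig)

    return paths
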