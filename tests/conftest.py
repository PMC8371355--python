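import numpy as np
import pytest

from kineticgfr import KineticParams


@pytest.fixture
def vignette():
    """The acute-injury vignette: baseline Cr 1.0 mg/dL, GFR dropped to
    10 mL/min, +6 L of fluid over 24 h on a 42 L volume."""
    return KineticParams.from_clinical(
        cr0=1.0, gen_ml_min=90.0, gfr_k_ml_min=10.0, v0=42.0, dv_dt_l_h=0.25
    )


@pytest.fixture
def low_cr_scenario():
    """Low initial creatinine at its steady-state GFR of 90 mL/min."""
    return KineticParams.from_clinical(
        cr0=1.0, gen_ml_min=90.0, gfr_k_ml_min=90.0, v0=42.0, dv_dt_l_h=0.25
    )


@pytest.fixture
def high_cr_scenario():
    """High initial creatinine (9.0 mg/dL) with GFR at 10 mL/min."""
    return KineticParams.from_clinical(
        cr0=9.0, gen_ml_min=90.0, gfr_k_ml_min=10.0, v0=42.0, dv_dt_l_h=0.25
    )


def random_valid_params(rng: np.random.Generator, t_max: float = 72.0,
                        avoid_singular: float = 0.0):
    """Draw one clinically valid (params, t) pair.

    ``avoid_singular`` keeps |dv_dt| and |gfr_k + dv_dt| above the given
    floor, for derivatives that only exist on the general branch.
    """
    while True:
        cr0 = rng.uniform(0.2, 15.0)
        gen = rng.uniform(20.0, 150.0) * 0.06
        gfr = rng.uniform(0.0, 120.0) * 0.06
        v0 = rng.uniform(20.0, 60.0)
        t = rng.uniform(0.5, t_max)
        # stay away from rule E's depletion bound for numerical headroom
        dv = rng.uniform(-0.8 * v0 / t, 0.5)
        if avoid_singular and (
            abs(dv) < avoid_singular or abs(gfr + dv) < avoid_singular
        ):
            continue
        return KineticParams(cr0=cr0, gen=gen, gfr_k=gfr, v0=v0, dv_dt=dv), t
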