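"""Synthetic transwell experiments and plasma profiles with known truth.

Every estimator in the package is testable without external data: the
generator draws transfer clearances and an abluminal binding factor per
compound, runs the exact forward model, optionally applies multiplicative
lognormal measurement noise, and records the ground-truth steady-state
ratio R_ss_true = PS_in/PS_out next to the simulated measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .invivo import ConcentrationProfile
from .transwell import (
    TransportParams,
    TranswellGeometry,
    TranswellMeasurement,
    simulate_transwell,
)


@dataclass(frozen=True)
class SimulationDesign:
    """Design of a synthetic transwell study.

    Clearance ranges are sampled log-uniformly (µL/min); the binding factor
    ``B`` inflates the apparent abluminal volume, V_app = V_ab·(1 + B).
    ``noise_cv`` is the coefficient of variation of multiplicative lognormal
    measurement noise (0 = noiseless).  The seed is mandatory: the whole
    table is reproducible from it.
    """

    n_compounds: int
    seed: int
    ps_in_range: Tuple[float, float] = (2.0, 50.0)
    ps_out_range: Tuple[float, float] = (5.0, 100.0)
    binding_range: Tuple[float, float] = (0.0, 4.0)
    noise_cv: float = 0.0
    geometry: TranswellGeometry = field(default_factory=TranswellGeometry)
    C_d0: float = 2.0
    t: float = 60.0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise InvalidParameterError("n_compounds must be >= 1")
        for name in ("ps_in_range", "ps_out_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidParameterError(f"{name} must be positive and ordered")
        lo, hi = self.binding_range
        if not 0 <= lo <= hi:
            raise InvalidParameterError("binding_range must be >= 0 and ordered")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv cannot be negative")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_transwell_suite(design: SimulationDesign) -> pd.DataFrame:
    """Simulate one transwell measurement per compound with known truth.

    Returns a truth table with one row per compound: the true PS_in, PS_out,
    V_app and R_ss_true, and the (optionally noisy) measured C_d0, C_d_t,
    C_r_t at the design sampling time.  Deterministic given the seed; with
    ``noise_cv = 0`` the measured columns satisfy the forward model's mass
    conservation exactly.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_compounds
    ps_in = np.exp(
        rng.uniform(np.log(design.ps_in_range[0]), np.log(design.ps_in_range[1]), n)
    )
    ps_out = np.exp(
        rng.uniform(np.log(design.ps_out_range[0]), np.log(design.ps_out_range[1]), n)
    )
    B = rng.uniform(design.binding_range[0], design.binding_range[1], n)
    v_app = design.geometry.V_ab * (1.0 + B)

    rows = []
    for i in range(n):
        params = TransportParams(PS_in=ps_in[i], PS_out=ps_out[i], V_app=v_app[i])
        sim = simulate_transwell(params, design.geometry, design.C_d0, [design.t])
        rows.append((sim["C_donor"].iloc[0], sim["C_receiver"].iloc[0]))
    c_d_t = np.array([r[0] for r in rows])
    c_r_t = np.array([r[1] for r in rows])

    noise = _lognormal_noise(rng, design.noise_cv, 3 * n).reshape(3, n)
    meas_d0 = design.C_d0 * noise[0]
    meas_d_t = np.minimum(c_d_t * noise[1], meas_d0)  # donor cannot grow
    meas_r_t = c_r_t * noise[2]

    return pd.DataFrame(
        {
            "compound": [f"SYN{i+1:04d}" for i in range(n)],
            "PS_in_true": ps_in,
            "PS_out_true": ps_out,
            "V_app_true": v_app,
            "R_ss_true": ps_in / ps_out,
            "C_d0": meas_d0,
            "C_d_t": meas_d_t,
            "C_r_t": meas_r_t,
            "t_min": design.t,
        }
    )


def measurements_from_truth(table: pd.DataFrame) -> List[TranswellMeasurement]:
    """Convert truth-table rows to measurement objects."""
    return [
        TranswellMeasurement(
            C_d0=row.C_d0, C_d_t=row.C_d_t, C_r_t=row.C_r_t, t=row.t_min
        )
        for row in table.itertuples()
    ]


def generate_plasma_profile(
    C_ss: float,
    half_life: float,
    times: Sequence[float],
    seed: Optional[int] = None,
    noise_cv: float = 0.0,
) -> ConcentrationProfile:
    """Free-plasma profile rising mono-exponentially to steady state.

    C(t) = C_ss·(1 - e^(-ln2·t/half_life)); by 3.5 half-lives the profile
    reaches ~91 % of the plateau, the conventional steady-state criterion
    for constant-rate infusion.  Optional multiplicative lognormal noise
    with the given CV, reproducible from the seed.
    """
    if C_ss <= 0 or half_life <= 0:
        raise InvalidParameterError("C_ss and half_life must be positive")
    t = np.asarray(times, dtype=float)
    values = C_ss * -np.expm1(-np.log(2.0) * t / half_life)
    if noise_cv > 0:
        if seed is None:
            raise InvalidParameterError("a seed is required for noisy profiles")
        rng = np.random.default_rng(seed)
        values = values * _lognormal_noise(rng, noise_cv, t.size)
    return ConcentrationProfile(times=t, values=values, kind="plasma-free")
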