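"""Transwell blood-brain-barrier assay: forward model and ratio estimation.

The assay is a two-compartment insert experiment: drug is dosed at a nominal
2 µM into the luminal ("blood", donor) compartment of an endothelial/glial
co-culture and both compartments are sampled after one hour.  Two unbound
brain/plasma ratio estimates come out of that single experiment:

* ``R_1h`` — the raw receiver/donor concentration ratio at 1 h, a
  non-steady-state snapshot of brain penetration;
* ``R_ss`` — an extrapolated steady-state ratio, the in vitro analogue of
  the in vivo Kp,uu measured under constant-rate infusion.

The steady-state extrapolation implemented here treats the donor decline
over 0-1 h as a single exponential driven by influx clearance and fits the
receiver exit rate so the receiver solution passes through the 1-h
measurement; the plateau ratio is then CL_in/CL_out.  It is a deliberately
simple single-timepoint estimator: backflux and abluminal binding are lumped
into the receiver exit clearance, an approximation that is good while the
receiver concentration is small relative to the donor.

Monolayer integrity is checked with a ¹⁴C-sucrose tracer; inserts whose
sucrose permeability exceeds 0.5·10⁻³ cm/min are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    DegenerateMeasurementError,
    EstimationFailureError,
    InvalidParameterError,
    NonIdentifiableError,
)

#: sucrose permeability threshold for an intact monolayer, cm/min
SUCROSE_PE_THRESHOLD = 5e-4

#: root-finding bracket for the receiver relaxation rate, 1/min
MU_BRACKET = (1e-8, 10.0)


@dataclass(frozen=True)
class TranswellGeometry:
    """Insert geometry and compartment fill volumes.

    Parameters
    ----------
    V_lum : float
        Luminal (donor) volume, µL.
    V_ab : float
        Abluminal (receiver) free volume, µL.
    A : float
        Insert membrane area, cm².  Defaults to the 4.7 cm² filter of the
        six-well co-culture format.
    """

    V_lum: float = 1500.0
    V_ab: float = 2500.0
    A: float = 4.7

    def __post_init__(self) -> None:
        for name in ("V_lum", "V_ab", "A"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TransportParams:
    """Mechanistic transfer parameters of the forward model.

    PS_in and PS_out are permeability-surface clearances (µL/min) in the
    luminal→abluminal and abluminal→luminal directions; V_app is the
    apparent abluminal distribution volume (µL), the free volume inflated
    by glial and nonspecific binding.
    """

    PS_in: float
    PS_out: float
    V_app: float

    def __post_init__(self) -> None:
        if self.PS_in < 0:
            raise InvalidParameterError("PS_in must be nonnegative")
        if not self.PS_out > 0:
            raise InvalidParameterError("PS_out must be strictly positive")
        if not self.V_app > 0:
            raise InvalidParameterError("V_app must be strictly positive")

    @property
    def R_ss_true(self) -> float:
        """Open-system steady-state unbound ratio PS_in/PS_out."""
        return self.PS_in / self.PS_out


@dataclass(frozen=True)
class TranswellMeasurement:
    """One compound's donor/receiver readout from a single insert.

    Concentrations in µM, sampling time ``t`` in minutes.
    ``sucrose_receiver_frac`` is the receiver/donor fraction of the
    ¹⁴C-sucrose tracer at time ``t`` (optional; required for QC).
    """

    C_d0: float
    C_d_t: float
    C_r_t: float
    t: float = 60.0
    sucrose_receiver_frac: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.C_d0 > 0:
            raise InvalidParameterError("C_d0 must be strictly positive")
        if self.C_r_t < 0:
            raise InvalidParameterError("C_r_t must be nonnegative")
        if self.C_d_t > self.C_d0:
            raise InvalidParameterError("C_d_t cannot exceed C_d0")
        if not self.t > 0:
            raise InvalidParameterError("sampling time t must be positive")


@dataclass(frozen=True)
class TransportEstimate:
    """Fitted kinetic constants and the derived unbound ratios.

    lambda_donor and mu_receiver are first-order rate constants (1/min);
    CL_in = lambda_donor·V_lum and CL_out = mu_receiver·V_ab are the
    corresponding clearances (µL/min); R_1h is the 1-h receiver/donor ratio
    and R_ss = CL_in/CL_out the extrapolated steady-state unbound ratio.
    """

    lambda_donor: float
    CL_in: float
    mu_receiver: float
    CL_out: float
    R_1h: float
    R_ss: float


@dataclass(frozen=True)
class SucroseQC:
    """Monolayer-integrity result from the sucrose tracer.

    ``Pe`` is the endothelial permeability coefficient in cm/min; ``passed``
    is True when Pe is below ``threshold``.  Both are None when no tracer
    data were supplied — QC is then unavailable, never a silent pass.
    """

    Pe: Optional[float]
    passed: Optional[bool]
    threshold: float = SUCROSE_PE_THRESHOLD

    @property
    def available(self) -> bool:
        return self.Pe is not None


def simulate_transwell(
    params: TransportParams,
    geom: TranswellGeometry,
    C_d0: float,
    times: Sequence[float],
) -> pd.DataFrame:
    """Exact solution of the two-compartment transwell transfer model.

    Dynamics (concentrations; clearances in µL/min, volumes in µL)::

        dC_d/dt = -(PS_in·C_d - PS_out·C_r) / V_lum
        dC_r/dt = +(PS_in·C_d - PS_out·C_r) / V_app

    with C_r(0) = 0.  The tracked amount V_lum·C_d + V_app·C_r is conserved.
    The system has eigenvalues 0 and -k with k = PS_in/V_lum + PS_out/V_app,
    so the solution is a single-exponential relaxation to the closed-system
    equilibrium and is returned in closed form.

    Returns a DataFrame with columns ``time_min``, ``C_donor``, ``C_receiver``.
    """
    if not C_d0 > 0:
        raise InvalidParameterError("C_d0 must be strictly positive")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidParameterError("times must be a nonempty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise InvalidParameterError("times must be sorted and nonnegative")

    k = params.PS_in / geom.V_lum + params.PS_out / params.V_app
    # closed-system equilibrium: PS_in·C_d = PS_out·C_r plus mass conservation
    C_d_inf = C_d0 * geom.V_lum * params.PS_out / (
        geom.V_lum * params.PS_out + params.V_app * params.PS_in
    )
    C_r_inf = (params.PS_in / params.PS_out) * C_d_inf
    decay = np.exp(-k * t)
    C_d = C_d_inf + (C_d0 - C_d_inf) * decay
    C_r = C_r_inf * (1.0 - decay)
    return pd.DataFrame({"time_min": t, "C_donor": C_d, "C_receiver": C_r})


def ratio_one_hour(meas: TranswellMeasurement) -> float:
    """Receiver/donor concentration ratio at the sampling time.

    This is the non-steady-state in vitro Cu,br/Cu,pl estimate read
    directly off the 1-h aliquots.
    """
    if meas.C_d_t <= 0:
        raise DegenerateMeasurementError(
            "donor concentration at t must be positive to form a ratio"
        )
    return meas.C_r_t / meas.C_d_t


def _receiver_conc(mu: float, lam: float, scale: float, t: float) -> float:
    """Receiver concentration at time t for exit rate mu.

    C_r(t) = scale · (e^{-λt} - e^{-µt}) / (µ - λ), with the analytic limit
    scale·t·e^{-λt} as µ → λ.  Evaluated via expm1 for stability near the
    degenerate point.
    """
    delta = mu - lam
    if abs(delta * t) < 1e-12:
        return scale * t * math.exp(-lam * t)
    return scale * math.exp(-lam * t) * (-math.expm1(-delta * t)) / delta


def estimate_steady_state_ratio(
    meas: TranswellMeasurement, geom: TranswellGeometry
) -> TransportEstimate:
    """Extrapolate the steady-state unbound ratio from a 1-h measurement.

    Procedure:

    1. donor decline rate ``lambda = ln(C_d0/C_d_t)/t``; influx clearance
       ``CL_in = lambda·V_lum`` (backflux neglected over the first hour);
    2. with the donor forced to ``C_d0·e^{-lambda·tau}``, solve for the
       receiver exit rate ``mu > 0`` such that the receiver solution passes
       through the measured ``C_r_t`` at ``tau = t``; ``CL_out = mu·V_ab``;
    3. ``R_ss = CL_in/CL_out`` — the plateau receiver/donor ratio under a
       constant donor, mirroring the in vivo constant-rate-infusion steady
       state.

    Valid while C_r_t ≪ C_d_t; see the package methods note for the
    identifiability discussion.
    """
    if meas.C_d_t >= meas.C_d0:
        raise NonIdentifiableError(
            "no measurable donor decline (C_d_t >= C_d0): influx clearance "
            "is not identifiable from this measurement"
        )
    if meas.C_d_t <= 0:
        raise DegenerateMeasurementError("C_d_t must be positive")

    lam = math.log(meas.C_d0 / meas.C_d_t) / meas.t
    CL_in = lam * geom.V_lum
    R_1h = meas.C_r_t / meas.C_d_t

    if meas.C_r_t == 0:
        warnings.warn(
            "receiver concentration is zero: reporting R_ss = 0 "
            "(no receiver kinetics identifiable)",
            stacklevel=2,
        )
        return TransportEstimate(
            lambda_donor=lam,
            CL_in=CL_in,
            mu_receiver=math.inf,
            CL_out=math.inf,
            R_1h=0.0,
            R_ss=0.0,
        )

    scale = CL_in * meas.C_d0 / geom.V_ab

    def residual(mu: float) -> float:
        return _receiver_conc(mu, lam, scale, meas.t) - meas.C_r_t

    lo, hi = MU_BRACKET
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo < 0 or f_hi > 0:
        raise EstimationFailureError(
            f"no receiver exit rate in ({lo:g}, {hi:g}) 1/min reproduces "
            f"C_r_t = {meas.C_r_t:g} µM (residuals {f_lo:.3g}, {f_hi:.3g})"
        )
    mu = brentq(residual, lo, hi, xtol=1e-12)
    CL_out = mu * geom.V_ab
    return TransportEstimate(
        lambda_donor=lam,
        CL_in=CL_in,
        mu_receiver=mu,
        CL_out=CL_out,
        R_1h=R_1h,
        R_ss=CL_in / CL_out,
    )


def sucrose_qc(
    meas: TranswellMeasurement,
    geom: TranswellGeometry,
    threshold: float = SUCROSE_PE_THRESHOLD,
) -> SucroseQC:
    """Monolayer-integrity QC from the co-dosed sucrose tracer.

    Single-timepoint clearance form: Pe = (V_ab·frac)/(t·A) with the
    abluminal volume converted µL→mL (cm³), giving Pe in cm/min.  Inserts
    pass when Pe is strictly below ``threshold`` (default 0.5·10⁻³ cm/min).
    """
    frac = meas.sucrose_receiver_frac
    if frac is None:
        return SucroseQC(Pe=None, passed=None, threshold=threshold)
    if not 0 <= frac < 1:
        raise InvalidParameterError("sucrose_receiver_frac must be in [0, 1)")
    pe = (geom.V_ab * 1e-3) * frac / (meas.t * geom.A)
    return SucroseQC(Pe=pe, passed=pe < threshold, threshold=threshold)


def process_transwell_table(
    df: pd.DataFrame,
    geom: TranswellGeometry,
    pe_threshold: float = SUCROSE_PE_THRESHOLD,
) -> pd.DataFrame:
    """Estimate ratios for a table of transwell measurements.

    Expects columns ``compound, C_d0, C_d_t, C_r_t, t_min, sucrose_frac``
    (``sucrose_frac`` may be missing/NaN: QC is then unavailable and the row
    is kept but flagged).  Rows that fail the sucrose QC are excluded from
    estimation; exclusions are logged, never silent.  Raises if no row
    survives QC.
    """
    import logging

    log = logging.getLogger("kpuu")
    out_rows = []
    n_pass = 0
    for row in df.itertuples(index=False):
        frac = getattr(row, "sucrose_frac", None)
        if frac is not None and (isinstance(frac, float) and math.isnan(frac)):
            frac = None
        meas = TranswellMeasurement(
            C_d0=row.C_d0,
            C_d_t=row.C_d_t,
            C_r_t=row.C_r_t,
            t=row.t_min,
            sucrose_receiver_frac=frac,
        )
        qc = sucrose_qc(meas, geom, threshold=pe_threshold)
        rec = {
            "compound": row.compound,
            "Pe_sucrose_cm_min": qc.Pe,
            "qc_pass": qc.passed,
        }
        if qc.passed is False:
            log.warning(
                "%s excluded: sucrose Pe %.3g cm/min >= threshold %.3g",
                row.compound,
                qc.Pe,
                pe_threshold,
            )
            rec.update({"R_1h": math.nan, "R_ss": math.nan})
        else:
            n_pass += 1
            est = estimate_steady_state_ratio(meas, geom)
            rec.update({"R_1h": est.R_1h, "R_ss": est.R_ss})
        out_rows.append(rec)
    if n_pass == 0:
        raise EstimationFailureError("0 rows passed QC: nothing to estimate")
    return pd.DataFrame(out_rows)
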