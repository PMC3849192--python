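"""In vivo translation: unbound ratios, free-brain profiles, efficacy coverage.

Converts steady-state total brain/plasma concentrations into the unbound
ratio Kp,uu = (Ctot,br/Ctot,pl)·(fu,br/fu,pl), predicts free-brain
concentration-time profiles from free-plasma profiles and the two in vitro
ratios (1-h ratio early, steady-state ratio late), corrects microdialysis
concentrations for carrier-flow dilution, and relates predicted free brain
levels to an in vitro potency (IC50) across doses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import DegenerateMeasurementError, InvalidParameterError

#: residual cerebral blood volume, mL/g (vascular space of [14C]-sucrose)
V_VASC_DEFAULT = 0.013


@dataclass(frozen=True)
class ConcentrationProfile:
    """A free-concentration time series (times in min, values in nM)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "plasma-free"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0:
            raise InvalidParameterError("profile must contain at least one point")
        if t.shape != v.shape or t.ndim != 1:
            raise InvalidParameterError("times and values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(v < 0):
            raise InvalidParameterError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class InVivoRecord:
    """Steady-state in vivo exposure for one compound.

    ``C_tot_br`` is the total brain concentration after vascular correction,
    ``C_tot_pl`` the total plasma concentration (both µM); fu values are the
    in vitro determined unbound fractions.  ``at_steady_state`` flags that
    the infusion ran for at least 3.5 half-lives.
    """

    C_tot_br: float
    C_tot_pl: float
    fu_br: float
    fu_pl: float
    at_steady_state: bool = True

    def __post_init__(self) -> None:
        if self.C_tot_br < 0 or self.C_tot_pl < 0:
            raise InvalidParameterError("concentrations must be nonnegative")
        for name in ("fu_br", "fu_pl"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidParameterError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class MicrodialysisSettings:
    """Probe flow rates, µL/min: slow dialysate plus water carrier flow."""

    F_dialysate: float = 0.15
    F_carrier: float = 0.80

    def __post_init__(self) -> None:
        if not self.F_dialysate > 0:
            raise InvalidParameterError("F_dialysate must be positive")
        if self.F_carrier < 0:
            raise InvalidParameterError("F_carrier cannot be negative")

    @property
    def dilution_factor(self) -> float:
        return (self.F_dialysate + self.F_carrier) / self.F_dialysate


@dataclass(frozen=True)
class FoldComparison:
    """Per-timepoint fold agreement between two aligned profiles."""

    times: np.ndarray
    fold: np.ndarray
    within: np.ndarray
    k: float
    violating_times: List[float]
    excluded_times: List[float]

    @property
    def n_compared(self) -> int:
        return int(self.within.size)

    @property
    def all_within(self) -> bool:
        return bool(np.all(self.within))


@dataclass(frozen=True)
class EfficacyAssessment:
    """Dose-wise predicted free brain exposure relative to an IC50."""

    IC50: float
    Cu_pl_ss: List[float]
    R_ss_invitro: float
    Cu_br_pred: List[float]
    coverage: List[float]
    doses: Optional[List[float]] = None
    effect_anticipated: List[bool] = field(default_factory=list)


def correct_vascular(
    C_br_raw: float, C_pl: float, V_vasc: float = V_VASC_DEFAULT
) -> float:
    """Subtract drug in residual cerebral blood from a raw brain measurement.

    ``C_br_raw - V_vasc·C_pl``, floored at zero with a warning (plasma
    concentration stands in for whole-blood concentration).  Default
    V_vasc = 0.013 mL/g.
    """
    if C_br_raw < 0 or C_pl < 0 or V_vasc < 0:
        raise InvalidParameterError("inputs must be nonnegative")
    corrected = C_br_raw - V_vasc * C_pl
    if corrected < 0:
        warnings.warn(
            "vascular correction exceeds the raw brain concentration; "
            "flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def kpuu_in_vivo(rec: InVivoRecord) -> float:
    """In vivo unbound ratio: Cu,br/Cu,pl = (Cbr/Cpl)·(fu,br/fu,pl)."""
    if rec.C_tot_pl <= 0:
        raise DegenerateMeasurementError(
            "total plasma concentration must be positive to form a ratio"
        )
    return (rec.C_tot_br / rec.C_tot_pl) * (rec.fu_br / rec.fu_pl)


def predict_free_brain_profile(
    plasma: ConcentrationProfile,
    R_1h: float,
    R_ss: float,
    t_early: float = 60.0,
    t_late: float = 120.0,
) -> ConcentrationProfile:
    """Predict a free-brain profile from a free-plasma profile.

    Early timepoints (t ≤ 60 min) use the 1-h in vitro ratio; timepoints at
    2 h and beyond, taken to represent steady state, use the in vitro
    steady-state ratio; the applied ratio is interpolated linearly in time
    in between, so the prediction is continuous at both knots.
    """
    if R_1h < 0 or R_ss < 0:
        raise InvalidParameterError("ratios must be nonnegative")
    ratio = np.interp(plasma.times, [t_early, t_late], [R_1h, R_ss])
    return ConcentrationProfile(
        times=plasma.times.copy(),
        values=ratio * plasma.values,
        kind="brain-free-predicted",
    )


def correct_microdialysis_dilution(
    raw: ConcentrationProfile, s: MicrodialysisSettings = MicrodialysisSettings()
) -> ConcentrationProfile:
    """Undo carrier-flow dilution of microdialysate concentrations.

    Every value is multiplied by (F_dialysate + F_carrier)/F_dialysate; at
    the default flows of 0.15 and 0.80 µL/min the factor is 19/3 ≈ 6.33.
    """
    return ConcentrationProfile(
        times=raw.times.copy(),
        values=raw.values * s.dilution_factor,
        kind=raw.kind,
    )


def fold_comparison(
    pred: ConcentrationProfile, obs: ConcentrationProfile, k: float = 3.0
) -> FoldComparison:
    """Per-timepoint within-k-fold agreement of two aligned profiles.

    Profiles must share identical sampling times (no resampling).  A pair
    is within k-fold when max(pred/obs, obs/pred) ≤ k (boundary inclusive).
    Timepoints where exactly one value is zero are incomparable and are
    excluded with a warning; both-zero timepoints count as within.
    """
    if k < 1:
        raise InvalidParameterError("fold threshold k must be >= 1")
    if pred.times.shape != obs.times.shape or not np.array_equal(
        pred.times, obs.times
    ):
        raise InvalidParameterError(
            "profiles must be aligned on identical timepoints"
        )
    p, o = pred.values, obs.values
    comparable = (p > 0) & (o > 0)
    both_zero = (p == 0) & (o == 0)
    excluded = ~comparable & ~both_zero
    if np.any(excluded):
        warnings.warn(
            f"{int(excluded.sum())} timepoint(s) with a single zero value "
            "are incomparable and excluded from the fold summary",
            stacklevel=2,
        )
    keep = comparable | both_zero
    times = pred.times[keep]
    fold = np.ones(keep.sum())
    cmp_mask = comparable[keep]
    pc, oc = p[keep][cmp_mask], o[keep][cmp_mask]
    fold[cmp_mask] = np.maximum(pc / oc, oc / pc)
    within = fold <= k
    return FoldComparison(
        times=times,
        fold=fold,
        within=within,
        k=k,
        violating_times=list(times[~within]),
        excluded_times=list(pred.times[excluded]),
    )


def efficacy_coverage(
    R_ss: float,
    Cu_pl_per_dose: Sequence[float],
    IC50: float,
    doses: Optional[Sequence[float]] = None,
) -> EfficacyAssessment:
    """Predicted free-brain exposure and IC50 coverage per dose.

    Cu,br(pred) = R_ss·Cu,pl; coverage = Cu,br(pred)/IC50.  Doses whose
    coverage reaches 1 are flagged as pharmacologically covered.
    """
    if IC50 <= 0:
        raise InvalidParameterError("IC50 must be positive")
    if R_ss < 0:
        raise InvalidParameterError("R_ss must be nonnegative")
    cu_pl = [float(c) for c in Cu_pl_per_dose]
    if any(c <= 0 for c in cu_pl):
        raise InvalidParameterError("free plasma concentrations must be positive")
    cu_br = [R_ss * c for c in cu_pl]
    cov = [c / IC50 for c in cu_br]
    return EfficacyAssessment(
        IC50=IC50,
        Cu_pl_ss=cu_pl,
        R_ss_invitro=R_ss,
        Cu_br_pred=cu_br,
        coverage=cov,
        doses=list(doses) if doses is not None else None,
        effect_anticipated=[c >= 1 for c in cov],
    )
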