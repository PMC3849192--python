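"""Fraction-unbound assays: plasma dialysis, brain homogenate, brain slice.

Three independent assays feed the in vivo unbound-ratio calculation:

* plasma equilibrium dialysis → fu,pl (buffer/plasma signal ratio);
* diluted brain-homogenate equilibrium dialysis → fu,br with the standard
  undiluted-tissue correction for the homogenate dilution factor D;
* brain-slice incubation → the unbound volume of distribution Vu,brain
  (mL/g) and its reciprocal fu,br, after subtracting the slice water
  adhesion volume V0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import AssayError, InvalidParameterError

#: slice water-adhesion volume, mL/g (inulin zero-time intercept)
V0_DEFAULT = 0.106

#: homogenate dilution factor for 10 % (w/v) brain homogenate
DILUTION_DEFAULT = 10.0


@dataclass(frozen=True)
class PlasmaDialysis:
    """Equilibrium-dialysis readout: analyte response on each side.

    Signals are MS peak areas (arbitrary units); only their ratio matters.
    """

    signal_buffer: float
    signal_plasma: float

    def __post_init__(self) -> None:
        if not self.signal_plasma > 0:
            raise AssayError("plasma-side signal must be strictly positive")
        if self.signal_buffer < 0:
            raise AssayError("buffer-side signal cannot be negative")


@dataclass(frozen=True)
class HomogenateDialysis:
    """Brain-homogenate dialysis readout with dilution factor D.

    D = 10 corresponds to a 10 % (w/v) homogenate; D = 1 disables the
    undiluted-tissue correction.
    """

    C_buffer: float
    C_homog: float
    D: float = DILUTION_DEFAULT

    def __post_init__(self) -> None:
        if not self.C_homog > 0:
            raise AssayError("homogenate-side concentration must be positive")
        if self.C_buffer < 0:
            raise AssayError("buffer-side concentration cannot be negative")
        if self.D < 1:
            raise InvalidParameterError("dilution factor D must be >= 1")


@dataclass(frozen=True)
class SliceIncubation:
    """Brain-slice incubation readout.

    ``C_slice`` is the amount of drug per gram of slice (µM-equivalent/g,
    already corrected for the slice-homogenization dilution); ``C_ECF`` is
    the buffer concentration, taken as the free concentration.  Use
    :meth:`from_homogenate` to build from a raw slice-homogenate
    concentration and dilution factor.
    """

    C_slice: float
    C_ECF: float
    V0: float = V0_DEFAULT

    def __post_init__(self) -> None:
        if not self.C_ECF > 0:
            raise AssayError("ECF (buffer) concentration must be positive")
        if self.C_slice < 0:
            raise AssayError("slice amount cannot be negative")
        if not 0 < self.V0 < 1:
            raise InvalidParameterError("V0 must lie in (0, 1) mL/g")

    @classmethod
    def from_homogenate(
        cls,
        C_slice_homog: float,
        C_ECF: float,
        D_slice: float = DILUTION_DEFAULT,
        V0: float = V0_DEFAULT,
    ) -> "SliceIncubation":
        """Build from the measured slice-homogenate concentration.

        Slices homogenized in (D_slice - 1) volumes of buffer are diluted
        D_slice-fold, so C_slice = D_slice · C_slice_homog.
        """
        if D_slice < 1:
            raise InvalidParameterError("D_slice must be >= 1")
        return cls(C_slice=D_slice * C_slice_homog, C_ECF=C_ECF, V0=V0)


class SliceResult(NamedTuple):
    """Slice-method output: Vu,brain (mL/g) and fu,brain = 1/Vu,brain."""

    Vu_brain: float
    fu_brain: float


def fu_plasma(d: PlasmaDialysis) -> float:
    """Fraction unbound in plasma: buffer/plasma signal ratio.

    Values above 1 (buffer signal exceeding plasma signal) are physically
    impossible at equilibrium and are clipped to 1 with a warning; a zero
    buffer signal returns 0 with a below-quantification warning.
    """
    if d.signal_buffer == 0:
        warnings.warn(
            "buffer signal is zero: fu,pl reported as 0 (below quantification)",
            stacklevel=2,
        )
        return 0.0
    fu = d.signal_buffer / d.signal_plasma
    if fu > 1:
        warnings.warn(
            f"fu,pl = {fu:.3g} exceeds 1; clipped to 1 (check assay)",
            stacklevel=2,
        )
        return 1.0
    return fu


def fu_brain_homogenate(d: HomogenateDialysis) -> float:
    """Fraction unbound in brain from diluted-homogenate dialysis.

    The apparent unbound fraction fu_app = C_buffer/C_homog refers to the
    D-fold diluted tissue; the undiluted value is recovered with

        fu = (1/D) / ((1/fu_app - 1) + 1/D)

    which is the identity for D = 1.
    """
    fu_app = d.C_buffer / d.C_homog
    if fu_app > 1:
        warnings.warn(
            f"apparent fu = {fu_app:.3g} exceeds 1; clipped to 1 (check assay)",
            stacklevel=2,
        )
        fu_app = 1.0
    if fu_app <= 0:
        raise AssayError(
            "apparent unbound fraction is zero: binding too strong to "
            "quantify at this dilution"
        )
    inv_D = 1.0 / d.D
    return inv_D / ((1.0 / fu_app - 1.0) + inv_D)


def fu_brain_slice(s: SliceIncubation) -> SliceResult:
    """Unbound volume of distribution and fraction unbound from a slice.

        Vu,brain = C_slice/C_ECF - V0        [mL/g]
        fu,brain = 1/Vu,brain

    V0 removes the buffer film adhering to the slice surface, so uptake at
    or below V0 is indistinguishable from adherent water and raises an
    error.  fu,brain > 1 (Vu < 1 mL/g) is physically odd but is returned
    with a warning rather than rejected.
    """
    ratio = s.C_slice / s.C_ECF
    if ratio <= s.V0:
        raise AssayError(
            f"slice/buffer ratio {ratio:.4g} does not exceed the water "
            f"adhesion volume V0 = {s.V0}: uptake indistinguishable from "
            "adherent buffer"
        )
    vu = ratio - s.V0
    fu = 1.0 / vu
    if fu > 1:
        warnings.warn(
            f"fu,brain = {fu:.3g} exceeds 1 (Vu,brain < 1 mL/g); possible "
            "assay artifact",
            stacklevel=2,
        )
    return SliceResult(Vu_brain=vu, fu_brain=fu)


def cu_brain_from_total(fu_brain: float, C_tot_brain: float) -> float:
    """Unbound brain concentration from the total and fraction unbound."""
    if fu_brain < 0 or C_tot_brain < 0:
        raise InvalidParameterError("fu_brain and C_tot_brain must be >= 0")
    return fu_brain * C_tot_brain
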