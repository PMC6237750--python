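"""Forster resonance energy transfer: efficiency, overlap, R0, distance.

The donor here is IAEDANS attached to the fingers subdomain (V303C) and the
acceptor is a dabcyl dark quencher on the DNA substrate, so transfer shows
up as quenching of the 490 nm IAEDANS emission.  Efficiency is measured as
``E = 1 - F_DA/F_D`` and converted to an interprobe distance through

    E = R0^6 / (R0^6 + r^6),   r = R0 * ((1-E)/E)^(1/6)

with the Forster radius

    R0 [A] = 9.78e3 * (kappa^2 * eta^-4 * f_d * J)^(1/6)

where ``J = integral E_D(lambda) eps_A(lambda) lambda^4 dlambda`` is the
spectral overlap of the area-normalized donor emission with the acceptor
extinction, in M^-1 cm^3 (wavelength converted to cm internally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Spectrum",
    "FretParameters",
    "efret",
    "overlap_integral",
    "forster_radius",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "FretError",
]

NM_TO_CM = 1e-7


class FretError(ValueError):
    pass


@dataclass
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray  # nm
    values: np.ndarray  # emission (a.u.) or extinction (M^-1 cm^-1)
    kind: Literal["emission", "extinction"]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise FretError("wavelengths and values must be equal-length 1-D arrays")
        if len(self.wavelengths) < 2:
            raise FretError("spectrum needs >= 2 points")
        if np.any(self.wavelengths <= 0) or np.any(np.diff(self.wavelengths) <= 0):
            raise FretError("wavelengths must be positive and strictly increasing")
        if self.kind == "emission" and np.any(self.values < 0):
            raise FretError("emission intensities must be >= 0")


@dataclass(frozen=True)
class FretParameters:
    """Photophysical constants entering R0.

    kappa2 = 2/3 is the dynamic isotropic orientation average; eta is the
    solution refractive index (1.344 for the Tris buffer used); f_d is the
    donor quantum yield without acceptor (0.7 for IAEDANS).
    """

    kappa2: float = 2.0 / 3.0
    eta: float = 1.344
    f_d: float = 0.7
    J: float | None = None  # M^-1 cm^3
    R0: float | None = None  # Angstrom

    def __post_init__(self) -> None:
        if self.kappa2 <= 0 or self.kappa2 > 4:
            raise FretError("kappa2 must be in (0, 4]")
        if self.eta <= 0 or self.f_d <= 0:
            raise FretError("eta and f_d must be > 0")


def efret(F_DA: float, F_D: float) -> float:
    """Transfer efficiency from donor quenching, ``1 - F_DA/F_D``.

    Noise can push the ratio outside [0, 1]; the raw value is returned with
    a warning rather than silently clipped.
    """
    if F_D <= 0:
        raise FretError("donor-only fluorescence F_D must be > 0")
    if F_DA < 0:
        raise FretError("F_DA must be >= 0")
    e = 1.0 - F_DA / F_D
    if not (0.0 <= e <= 1.0):
        warnings.warn(f"FRET efficiency {e:.4f} outside [0, 1]; check baselines")
    return e


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_extinction: Spectrum,
    *,
    normalize_donor: bool = True,
) -> float:
    """Spectral overlap J in M^-1 cm^3 by trapezoidal quadrature.

    Both spectra are linearly interpolated onto the union grid of their
    common wavelength support.  The donor emission is normalized to unit
    area over that support (in cm) unless ``normalize_donor=False``.
    """
    if donor_emission.kind != "emission" or acceptor_extinction.kind != "extinction":
        raise FretError("expected (emission, extinction) spectra in that order")
    lo = max(donor_emission.wavelengths[0], acceptor_extinction.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_extinction.wavelengths[-1])
    if lo >= hi:
        raise FretError("spectra have disjoint wavelength supports")
    grid = np.union1d(donor_emission.wavelengths, acceptor_extinction.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    ed = np.interp(grid, donor_emission.wavelengths, donor_emission.values)
    ea = np.interp(grid, acceptor_extinction.wavelengths, acceptor_extinction.values)
    lam_cm = grid * NM_TO_CM
    if normalize_donor:
        area = np.trapezoid(ed, lam_cm)
        if area <= 0:
            raise FretError("donor emission has zero area on the common support")
        ed = ed / area
    return float(np.trapezoid(ed * ea * lam_cm**4, lam_cm))


def forster_radius(params: FretParameters) -> float:
    """R0 in Angstrom from kappa^2, eta, f_d and J (M^-1 cm^3)."""
    if params.J is None or params.J <= 0:
        raise FretError("a positive overlap integral J is required")
    factor = params.kappa2 * params.eta**-4 * params.f_d * params.J
    if factor <= 0:
        raise FretError("kappa^2 * eta^-4 * f_d * J must be > 0")
    return 9.78e3 * factor ** (1.0 / 6.0)


def distance_from_efficiency(E: float, R0: float) -> float:
    """Interprobe distance r = R0 ((1-E)/E)^(1/6); r = R0 at E = 0.5."""
    if not (0.0 < E < 1.0):
        raise FretError("efficiency must lie strictly in (0, 1)")
    if R0 <= 0:
        raise FretError("R0 must be > 0")
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def efficiency_from_distance(r: float, R0: float) -> float:
    """Forward law E = R0^6 / (R0^6 + r^6)."""
    if r <= 0 or R0 <= 0:
        raise FretError("r and R0 must be > 0")
    return R0**6 / (R0**6 + r**6)
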