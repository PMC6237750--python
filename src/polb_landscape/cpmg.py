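"""CPMG relaxation dispersion: fast-exchange fitting and flexibility calls.

A methyl group exchanging between two environments on the millisecond
timescale shows an effective transverse relaxation rate that depends on the
CPMG pulse spacing tau_cp:

    R2(1/tau_cp) = R2_0 + R_ex * [1 - 2 tanh(k_ex tau_cp / 2) / (k_ex tau_cp)]

with, in the fast-exchange limit, ``R_ex = p_a p_b d_omega^2 / k_ex``
(populations p_a + p_b = 1, chemical-shift difference d_omega in rad/s,
exchange rate k_ex in 1/s).  Rapid pulsing (tau_cp -> 0) refocuses the
exchange contribution entirely (R2 -> R2_0); slow pulsing lets it relax
fully (R2 -> R2_0 + R_ex).

A residue is called "flexible" when (i) the dispersive model is preferred
over a flat line (an F-test on the nested models at alpha = 0.05 by
default) and (ii) the fitted R_ex exceeds 2 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DispersionCurve",
    "DispersionFit",
    "r2_model",
    "rex_from_populations",
    "fit_dispersion",
    "count_flexible",
    "CpmgError",
    "REX_FLEXIBLE_CUTOFF",
]

#: R_ex (1/s) above which a dispersive residue is called flexible.
REX_FLEXIBLE_CUTOFF = 2.0


class CpmgError(ValueError):
    pass


@dataclass
class DispersionCurve:
    """R2_eff versus pulsing rate 1/tau_cp for one residue.

    ``from_nu_cpmg`` accepts the spectrometer's nu_CPMG (Hz) grid instead,
    using tau_cp = 1/(2 nu_CPMG) (tau_cp = spacing between successive
    180-degree pulses).
    """

    residue_key: str
    tau_cp_inverse: np.ndarray  # 1/s
    R2_eff: np.ndarray  # 1/s
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tau_cp_inverse = np.asarray(self.tau_cp_inverse, dtype=float)
        self.R2_eff = np.asarray(self.R2_eff, dtype=float)
        if self.tau_cp_inverse.shape != self.R2_eff.shape or self.tau_cp_inverse.ndim != 1:
            raise CpmgError("grids must be equal-length 1-D arrays")
        if np.any(self.tau_cp_inverse <= 0) or np.any(np.diff(self.tau_cp_inverse) <= 0):
            raise CpmgError("1/tau_cp grid must be positive and increasing")
        if not np.all(np.isfinite(self.R2_eff)):
            raise CpmgError("R2_eff must be finite")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.R2_eff.shape or np.any(self.uncertainties <= 0):
                raise CpmgError("uncertainties must be positive, same shape as R2_eff")

    @classmethod
    def from_nu_cpmg(
        cls, residue_key: str, nu_cpmg_hz, R2_eff, uncertainties=None
    ) -> "DispersionCurve":
        nu = np.asarray(nu_cpmg_hz, dtype=float)
        return cls(residue_key, 2.0 * nu, np.asarray(R2_eff, float), uncertainties)


@dataclass(frozen=True)
class DispersionFit:
    residue_key: str
    R2_0: float
    R_ex: float
    k_ex: float | None
    model_choice: Literal["flat", "dispersive"]
    p_value: float | None
    flexible: bool
    criterion: str = "ftest"


def r2_model(tau_cp_inverse, R2_0: float, R_ex: float, k_ex: float):
    """Fast-exchange dispersion profile, defined by its limits at the ends.

    Uses the numerically safe evaluation of ``2 tanh(x)/ (2x)`` with
    ``x = k_ex tau_cp / 2`` (-> 1 as tau_cp -> 0, -> 0 as tau_cp -> inf).
    """
    if R2_0 <= 0 or R_ex < 0 or k_ex <= 0:
        raise CpmgError("require R2_0 > 0, R_ex >= 0, k_ex > 0")
    inv = np.asarray(tau_cp_inverse, dtype=float)
    if np.any(inv <= 0):
        raise CpmgError("1/tau_cp must be > 0")
    x = k_ex / (2.0 * inv)  # = k_ex * tau_cp / 2
    with np.errstate(over="ignore"):
        bracket = 1.0 - np.where(x < 1e-8, 1.0 - x**2 / 3.0, np.tanh(x) / x)
    out = R2_0 + R_ex * bracket
    return out if out.ndim else float(out)


def rex_from_populations(p_a: float, p_b: float, delta_omega: float, k_ex: float) -> float:
    """Fast-exchange amplitude R_ex = p_a p_b d_omega^2 / k_ex (1/s)."""
    if abs(p_a + p_b - 1.0) > 1e-9:
        raise CpmgError("populations must sum to 1")
    if p_a < 0 or p_b < 0 or k_ex <= 0:
        raise CpmgError("populations must be >= 0 and k_ex > 0")
    return p_a * p_b * delta_omega**2 / k_ex


def fit_dispersion(
    curve: DispersionCurve,
    *,
    alpha: float = 0.05,
    rex_cutoff: float = REX_FLEXIBLE_CUTOFF,
    criterion: Literal["ftest", "aic"] = "ftest",
) -> DispersionFit:
    """Fit both the flat and dispersive models and call flexibility.

    The flat model is a constant R2_0 (its least-squares estimate is the
    weighted mean).  Model preference uses an F-test on the nested pair
    (2 extra parameters) at ``alpha``, or AIC when requested.  A residue is
    flexible iff the dispersive model is preferred AND R_ex > ``rex_cutoff``.
    Non-convergence of the dispersive fit falls back to the flat call.
    """
    inv = curve.tau_cp_inverse
    y = curve.R2_eff
    n = len(y)
    if n < 5:
        raise CpmgError("dispersion fit needs >= 5 grid points")
    w = None if curve.uncertainties is None else curve.uncertainties

    flat = float(np.average(y, weights=None if w is None else 1.0 / w**2))
    rss_flat = float(np.sum(((y - flat) / (1.0 if w is None else w)) ** 2))

    def model(x, r20, rex, kex):
        return r2_model(x, r20, max(rex, 0.0), max(kex, 1e-6))

    best = None
    rex0 = max(float(y.max() - y.min()), 0.1)
    for kex0 in (200.0, 600.0, 1500.0, 4000.0, 10000.0):
        try:
            popt, _ = curve_fit(
                model, inv, y,
                p0=[max(float(y.min()), 0.1), rex0, kex0],
                sigma=w, absolute_sigma=w is not None,
                bounds=([1e-6, 0.0, 1.0], [np.inf, np.inf, 1e7]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(((model(inv, *popt) - y) / (1.0 if w is None else w)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)

    if best is None:
        return DispersionFit(curve.residue_key, flat, 0.0, None, "flat", None, False, criterion)

    (r20, rex, kex), rss_disp = best
    p_extra, p_full = 2, 3
    if criterion == "ftest":
        if rss_disp <= 0 or n <= p_full:
            p_value = 0.0
        else:
            F = ((rss_flat - rss_disp) / p_extra) / (rss_disp / (n - p_full))
            p_value = float(stats.f.sf(max(F, 0.0), p_extra, n - p_full))
        dispersive = p_value < alpha
    elif criterion == "aic":
        aic_flat = n * math.log(max(rss_flat, 1e-300) / n) + 2 * 1
        aic_disp = n * math.log(max(rss_disp, 1e-300) / n) + 2 * p_full
        p_value = None
        dispersive = aic_disp < aic_flat
    else:
        raise CpmgError(f"unknown criterion {criterion!r}")

    if not dispersive:
        return DispersionFit(curve.residue_key, flat, 0.0, None, "flat", p_value, False, criterion)
    flexible = rex > rex_cutoff
    return DispersionFit(
        curve.residue_key, float(r20), float(rex), float(kex),
        "dispersive", p_value, bool(flexible), criterion,
    )


def count_flexible(fits: Iterable[DispersionFit]) -> int:
    """Number of residues passing the two-condition flexibility rule."""
    return sum(f.flexible for f in fits)
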