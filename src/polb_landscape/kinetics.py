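"""Pre-steady-state kinetics and nucleotide-incorporation fidelity.

Rapid chemical-quench progress curves for a DNA polymerase show biphasic
"burst" kinetics: a fast first turnover (rate ``k_obs``) from enzyme already
committed on the substrate, followed by a slower linear steady state
(``k_ss``) limited by product release.  Single-turnover time courses at each
dNTP concentration follow a single exponential; plotting the exponential
rate against [dNTP] and fitting a hyperbola yields ``k_pol`` (maximum
incorporation rate, 1/s) and ``K_d(dNTP)`` (apparent dissociation constant
of the incoming nucleotide, uM).

From paired correct/incorrect ``(k_pol, K_d)`` measurements the standard
fidelity arithmetic follows: catalytic efficiency ``k_pol / K_d``,
discrimination ratios, fidelity ``(eff_correct + eff_incorrect) /
eff_incorrect``, and the fold change in fidelity between two enzymes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ProgressCurve",
    "BurstFit",
    "SaturationFit",
    "FidelityRow",
    "FidelityTable",
    "burst_model",
    "fit_burst",
    "fit_single_exponential",
    "fit_saturation",
    "fidelity_metrics",
    "x_fold",
    "round_sig",
    "KineticsError",
    "FitFailure",
]


class KineticsError(ValueError):
    pass


class FitFailure(RuntimeError):
    """Nonlinear fit did not converge or the data cannot identify the model."""


@dataclass
class ProgressCurve:
    """Product concentration (nM) versus time (s)."""

    times: np.ndarray
    product: np.ndarray
    dNTP_concentration: float | None = None  # uM
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.shape != self.product.shape:
            raise KineticsError("times and product must have the same shape")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise KineticsError("need a 1-D curve with >= 2 points")
        if np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise KineticsError("times must be strictly increasing and >= 0")
        if not np.all(np.isfinite(self.product)):
            raise KineticsError("product values must be finite")


@dataclass(frozen=True)
class BurstFit:
    E_app: float  # nM, apparent active-enzyme amplitude
    k_obs: float  # 1/s, burst-phase rate
    k_ss: float  # 1/s, steady-state rate
    residual_norm: float
    form: str = "standard"


@dataclass(frozen=True)
class SaturationFit:
    k_pol: float  # 1/s
    K_d_dNTP: float  # uM
    kobs_points: tuple[tuple[float, float], ...] = ()
    residual_norm: float = 0.0
    ill_conditioned: bool = False


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def burst_model(
    t: np.ndarray | float,
    E_app: float,
    k_obs: float,
    k_ss: float,
    form: Literal["standard", "as_printed"] = "standard",
) -> np.ndarray | float:
    """Biphasic burst model for product formation.

    The standard form is

    ``E_app * [ (k_obs/(k_obs+k_ss))^2 * (1 - exp(-(k_obs+k_ss) t))
    + k_obs*k_ss/(k_obs+k_ss) * t ]``

    which reduces to a single exponential of amplitude ``E_app`` when
    ``k_ss = 0``.  ``form="as_printed"`` replaces the squared amplitude
    ratio by ``k_obs/(k_obs+k_ss)^2`` — a commonly transcribed variant kept
    for literal reproduction; it is not dimensionless in the amplitude and
    is not the default.
    """
    if k_obs <= 0 or k_ss < 0 or E_app <= 0:
        raise KineticsError("E_app and k_obs must be > 0, k_ss >= 0")
    t = np.asarray(t, dtype=float)
    s = k_obs + k_ss
    expo = 1.0 - np.exp(-s * t)
    lin = (k_obs * k_ss / s) * t
    if form == "standard":
        amp = (k_obs / s) ** 2
    elif form == "as_printed":
        amp = k_obs / s**2
    else:
        raise KineticsError(f"unknown burst form {form!r}")
    out = E_app * (amp * expo + lin)
    return out if out.ndim else float(out)


def _single_exp(t: np.ndarray, A: float, k: float) -> np.ndarray:
    return A * (1.0 - np.exp(-k * t))


def _hyperbola(c: np.ndarray, k_pol: float, K_d: float) -> np.ndarray:
    return k_pol * c / (K_d + c)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _multistart_fit(f, x, y, starts, bounds):
    """curve_fit over a grid of starts; return the best converged solution."""
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailure("no start converged")
    return best


def fit_burst(
    curve: ProgressCurve, form: Literal["standard", "as_printed"] = "standard"
) -> BurstFit:
    """Fit the biphasic burst model by multi-start nonlinear least squares.

    Starts are drawn from a log-spaced grid of rate pairs bracketing the
    observable window, with the amplitude seeded from the data.  A curve
    with no resolvable burst phase (k_obs collapsing onto k_ss or running
    into the grid ceiling) raises :class:`FitFailure`.
    """
    t, y = curve.times, curve.product
    if len(t) < 6:
        raise KineticsError("burst fit needs >= 6 time points")
    if _is_effectively_linear(t, y):
        raise FitFailure("curve is monotone-linear: burst phase unidentifiable")
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    amp0 = max(float(np.max(y)), 1e-6)

    def f(tt, E, ko, ks):
        return burst_model(tt, E, ko, ks, form=form)

    rate_lo, rate_hi = 0.01 / span, 1000.0 / span
    grid = np.geomspace(rate_lo * 10, rate_hi / 10, 5)
    starts = [
        (amp0, ko, ks) for ko in grid for ks in grid if ko > ks
    ] or [(amp0, 10.0 / span, 1.0 / span)]
    bounds = ([1e-12, rate_lo, 0.0], [np.inf, rate_hi, rate_hi])
    popt, rss = _multistart_fit(f, t, y, starts, bounds)
    E, ko, ks = popt
    if ko > 0.99 * rate_hi:
        raise FitFailure("no resolvable burst phase (k_obs ran to the grid ceiling)")
    return BurstFit(E_app=float(E), k_obs=float(ko), k_ss=float(ks),
                    residual_norm=math.sqrt(rss), form=form)


def _is_effectively_linear(t: np.ndarray, y: np.ndarray) -> bool:
    # RSS of a straight line within 1% of total variance => no burst signal
    A = np.vstack([t, np.ones_like(t)]).T
    resid = np.linalg.lstsq(A, y, rcond=None)[1]
    rss = float(resid[0]) if resid.size else 0.0
    tot = float(np.sum((y - y.mean()) ** 2))
    return tot == 0 or rss / tot < 1e-2


def fit_single_exponential(curve: ProgressCurve) -> tuple[float, float]:
    """Fit ``A (1 - exp(-k_obs t))``; returns ``(A, k_obs)``."""
    t, y = curve.times, curve.product
    if len(t) < 4:
        raise KineticsError("single-exponential fit needs >= 4 points")
    amp0 = float(np.max(y))
    if amp0 <= 0 or np.allclose(y, y[0]):
        raise FitFailure("curve has no rise to fit")
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    starts = [(amp0, k) for k in np.geomspace(0.1 / span, 100.0 / span, 6)]
    bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    (A, k), _ = _multistart_fit(_single_exp, t, y, starts, bounds)
    return float(A), float(k)


def fit_saturation(
    kobs_points: Iterable[tuple[float, float]]
) -> SaturationFit:
    """Fit the hyperbola ``k_obs = k_pol [dNTP] / (K_d + [dNTP])``.

    At ``[dNTP] = K_d`` the model predicts ``k_pol / 2``.  If the sampled
    concentrations do not bracket the fitted K_d the result is flagged
    ``ill_conditioned`` (both parameters trade off along a ridge there).
    """
    pts = sorted((float(c), float(k)) for c, k in kobs_points)
    if len(pts) < 3:
        raise KineticsError("saturation fit needs >= 3 concentrations")
    c = np.array([p[0] for p in pts])
    k = np.array([p[1] for p in pts])
    if np.any(c <= 0):
        raise KineticsError("concentrations must be > 0")
    kmax0 = float(np.max(k))
    starts = [(kmax0, kd) for kd in np.geomspace(c[0] / 10, c[-1] * 10, 7)]
    (k_pol, K_d), rss = _multistart_fit(
        _hyperbola, c, k, starts, ([1e-12, 1e-12], [np.inf, np.inf])
    )
    ill = not (c[0] <= K_d <= c[-1])
    return SaturationFit(
        k_pol=float(k_pol),
        K_d_dNTP=float(K_d),
        kobs_points=tuple(pts),
        residual_norm=math.sqrt(rss),
        ill_conditioned=bool(ill),
    )


# ---------------------------------------------------------------------------
# fidelity arithmetic
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for as-printed efficiencies)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")


@dataclass(frozen=True)
class FidelityRow:
    """Derived fidelity metrics for one correct/incorrect base-pair pairing."""

    template_base: str
    enzyme: str
    k_pol_correct: float
    K_d_correct: float
    k_pol_incorrect: float
    K_d_incorrect: float
    D_kpol: float
    D_Kd: float
    efficiency_correct: float  # uM^-1 s^-1
    efficiency_incorrect: float
    fidelity: float
    x_fold: float | None = None


def fidelity_metrics(
    correct: tuple[float, float],
    incorrect: tuple[float, float],
    rounding: Literal["as_printed", "none"] = "as_printed",
    *,
    template_base: str = "",
    enzyme: str = "",
) -> FidelityRow:
    """Discrimination, efficiency and fidelity from (k_pol, K_d) pairs.

    ``D_kpol = k_pol(correct)/k_pol(incorrect)``;
    ``D_Kd = K_d(incorrect)/K_d(correct)``; efficiency is ``k_pol/K_d``; and
    ``fidelity = (eff_correct + eff_incorrect)/eff_incorrect``.  In
    ``rounding="as_printed"`` mode each efficiency is rounded to two
    significant figures before the fidelity quotient, matching how such
    tables are conventionally typeset; ``"none"`` keeps full precision.
    """
    kc, Kc = correct
    ki, Ki = incorrect
    if min(kc, Kc, ki, Ki) <= 0:
        raise KineticsError("all k_pol and K_d values must be > 0")
    eff_c = kc / Kc
    eff_i = ki / Ki
    if rounding == "as_printed":
        eff_c_q, eff_i_q = round_sig(eff_c), round_sig(eff_i)
    elif rounding == "none":
        eff_c_q, eff_i_q = eff_c, eff_i
    else:
        raise KineticsError(f"unknown rounding mode {rounding!r}")
    return FidelityRow(
        template_base=template_base,
        enzyme=enzyme,
        k_pol_correct=kc,
        K_d_correct=Kc,
        k_pol_incorrect=ki,
        K_d_incorrect=Ki,
        D_kpol=kc / ki,
        D_Kd=Ki / Kc,
        efficiency_correct=eff_c_q,
        efficiency_incorrect=eff_i_q,
        fidelity=(eff_c_q + eff_i_q) / eff_i_q,
    )


def x_fold(fidelity_wt: float, fidelity_variant: float) -> float:
    """Fold loss of fidelity of a variant relative to wild type."""
    if fidelity_wt <= 0 or fidelity_variant <= 0:
        raise KineticsError("fidelities must be > 0")
    return fidelity_wt / fidelity_variant


@dataclass
class FidelityTable:
    """Fidelity rows for several template/enzyme pairings, with fold changes.

    ``from_measurements`` takes per-(template, enzyme) correct and incorrect
    (k_pol, K_d) pairs and fills every derived column, attaching the
    wild-type/variant fidelity ratio to the variant row of each template.
    """

    rows: list[FidelityRow] = field(default_factory=list)

    @classmethod
    def from_measurements(
        cls,
        measurements: Sequence[
            tuple[str, str, tuple[float, float], tuple[float, float]]
        ],
        rounding: Literal["as_printed", "none"] = "as_printed",
        reference_enzyme: str = "WT",
    ) -> "FidelityTable":
        rows = [
            fidelity_metrics(corr, inc, rounding, template_base=tb, enzyme=enz)
            for tb, enz, corr, inc in measurements
        ]
        by_template: dict[str, dict[str, FidelityRow]] = {}
        for r in rows:
            by_template.setdefault(r.template_base, {})[r.enzyme] = r
        out: list[FidelityRow] = []
        for r in rows:
            ref = by_template[r.template_base].get(reference_enzyme)
            if ref is not None and r.enzyme != reference_enzyme:
                r = FidelityRow(**{**r.__dict__, "x_fold": x_fold(ref.fidelity, r.fidelity)})
            out.append(r)
        return cls(rows=out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])
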