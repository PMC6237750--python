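"""Mass-action simulation and global fitting of the polymerase kinetic scheme.

The precatalytic pathway modeled here is

    E + D  <=>  E.D                    (k_p1 / k_m1, DNA binding)
    E.D + N  <=>  E.D.N                (k_p2 / k_m2, ground-state dNTP binding)
    E.D.N  <=>  E'.D.N                 (k_p3 / k_m3, fingers closing)
    E'.D.N  <=>  E''.D.N               (k_p4 / k_m4, second non-covalent step)
    E''.D.N  ->  E.Dp                  (k_p5, chemistry; reverse set to 0)
    E.Dp  <=>  E + P                   (k_p6 / k_m6, lumped product release)

Stopped-flow FRET reports on these steps through state-dependent donor
quenching; the observable is ``baseline + sum_i a_i * [species_i](t)``.

Fitting follows the constraint strategy used for such data: DNA binding is
fixed through its measured K_d, dNTP binding through K_d(dNTP), chemistry
through the independently measured k_pol, the chemistry reverse rate is
zero, and the conformational reverse rates k_m3/k_m4 are fixed from a trap
experiment, leaving the forward conformational rates (k_p3, k_p4) free.
Per-trace fluorescence amplitudes are nuisance parameters solved linearly
at each candidate rate set.

Concentration unit is uM throughout; bimolecular rate constants are
uM^-1 s^-1 (helpers convert from nM^-1 s^-1 where the field quotes DNA
binding that way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

from .kinetics import FitFailure

__all__ = [
    "Reaction",
    "KineticScheme",
    "FluorescenceTrace",
    "AmplitudeMap",
    "SimulationResult",
    "TrapFit",
    "GlobalFitResult",
    "default_scheme",
    "WT_RATES",
    "I260Q_RATES",
    "simulate",
    "signal_from_trajectories",
    "dead_time_mask",
    "fit_global",
    "fit_multi_exponential",
    "fit_triple_exponential",
    "MechanismError",
]

DEAD_TIME_DEFAULT = 0.002  # s, stopped-flow instrument dead time


class MechanismError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scheme definition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction ``reactants -> products`` at rate
    ``rate_name`` (unimolecular s^-1 or bimolecular uM^-1 s^-1)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_name: str

    def __post_init__(self) -> None:
        if len(self.reactants) not in (1, 2):
            raise MechanismError("only uni- and bimolecular reactions supported")


@dataclass
class KineticScheme:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    rates: dict[str, float]
    #: rate names that are held fixed during fitting
    constraints: frozenset[str] = frozenset()
    #: conserved moieties: name -> species containing that moiety (with unit
    #: stoichiometry); used for the mass-balance assertion after simulation
    moieties: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = set(self.species)
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in idx:
                    raise MechanismError(f"reaction references unknown species {s!r}")
            if r.rate_name not in self.rates:
                raise MechanismError(f"rate {r.rate_name!r} has no value")
        for v in self.rates.values():
            if v < 0 or not math.isfinite(v):
                raise MechanismError("rate constants must be finite and >= 0")

    def with_rates(self, **updates: float) -> "KineticScheme":
        unknown = set(updates) - set(self.rates)
        if unknown:
            raise MechanismError(f"unknown rates {sorted(unknown)}")
        return replace(self, rates={**self.rates, **updates})


#: Rate set for the wild-type enzyme with correct dNTP on template G.
#: Fingers closing 124 s^-1 / opening 11.5 s^-1 and the second-step reverse
#: 4.05 s^-1 are measured values; chemistry 12.0 s^-1 is k_pol; DNA and dNTP
#: binding enter through K_d constraints (K_d(DNA) ~ 2 nM, K_d(dNTP) 1.5 uM)
#: with diffusion-scale association; k_p4 and product release are
#: representative placeholders (see docs/methods.md).
WT_RATES: dict[str, float] = {
    "k_p1": 100.0,  # uM^-1 s^-1 (= 0.1 nM^-1 s^-1)
    "k_m1": 0.2,  # = K_d(DNA) 0.002 uM x k_p1
    "k_p2": 100.0,  # uM^-1 s^-1, diffusion-scale dNTP association
    "k_m2": 150.0,  # = K_d(dNTP) 1.5 uM x k_p2
    "k_p3": 124.0,  # fingers closing
    "k_m3": 11.5,  # fingers opening
    "k_p4": 40.0,  # second non-covalent step (placeholder, "similar" WT/variant)
    "k_m4": 4.05,  # its reverse, from the trap experiment
    "k_p5": 12.0,  # chemistry, = k_pol
    "k_m5": 0.0,  # chemistry reverse, set to zero
    "k_p6": 1.3,  # lumped product release (~ steady-state rate)
    "k_m6": 0.01,  # uM^-1 s^-1, product rebinding
}

#: Mutator-variant rate set (template G, correct dNTP): slower closing
#: (4.73 s^-1), faster reverses (48.2, 163 s^-1), k_pol 3.6 s^-1, tighter
#: dNTP binding (K_d 0.6 uM), weaker DNA binding (K_d(DNA) ~ 5.75 nM).
I260Q_RATES: dict[str, float] = {
    **WT_RATES,
    "k_m1": 0.575,
    "k_m2": 60.0,
    "k_p3": 4.73,
    "k_m3": 48.2,
    "k_m4": 163.0,
    "k_p5": 3.6,
}

SPECIES = ("E", "D", "N", "ED", "EDN", "EcDN", "EccDN", "EDp", "P")

STANDARD_CONSTRAINTS = frozenset(
    {"k_p1", "k_m1", "k_p2", "k_m2", "k_m3", "k_m4", "k_p5", "k_m5"}
)


def default_scheme(
    enzyme: Literal["WT", "I260Q"] = "WT", *, include_release: bool = True
) -> KineticScheme:
    """The default precatalytic scheme with the standard constraint set.

    Species: E (free enzyme), D (gapped DNA), N (dNTP), ED (binary),
    EDN (open ternary), EcDN (closed ternary), EccDN (post-second-step
    ternary), EDp (product complex), P (released nicked DNA).
    """
    rates = dict(WT_RATES if enzyme == "WT" else I260Q_RATES)
    reactions = [
        Reaction(("E", "D"), ("ED",), "k_p1"),
        Reaction(("ED",), ("E", "D"), "k_m1"),
        Reaction(("ED", "N"), ("EDN",), "k_p2"),
        Reaction(("EDN",), ("ED", "N"), "k_m2"),
        Reaction(("EDN",), ("EcDN",), "k_p3"),
        Reaction(("EcDN",), ("EDN",), "k_m3"),
        Reaction(("EcDN",), ("EccDN",), "k_p4"),
        Reaction(("EccDN",), ("EcDN",), "k_m4"),
        Reaction(("EccDN",), ("EDp",), "k_p5"),
        Reaction(("EDp",), ("EccDN",), "k_m5"),
    ]
    if include_release:
        reactions += [
            Reaction(("EDp",), ("E", "P"), "k_p6"),
            Reaction(("E", "P"), ("EDp",), "k_m6"),
        ]
    else:
        for name in ("k_p6", "k_m6"):
            rates.pop(name, None)
    moieties = {
        "enzyme": ("E", "ED", "EDN", "EcDN", "EccDN", "EDp"),
        "dna": ("D", "ED", "EDN", "EcDN", "EccDN", "EDp", "P"),
    }
    return KineticScheme(
        species=SPECIES,
        reactions=tuple(reactions),
        rates=rates,
        constraints=STANDARD_CONSTRAINTS,
        moieties=moieties,
    )


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


@dataclass
class FluorescenceTrace:
    """A stopped-flow record: signal (a.u. or V) versus time (s)."""

    times: np.ndarray
    signal: np.ndarray
    dNTP_concentration: float = 0.0  # uM, post-mix
    dead_time: float = DEAD_TIME_DEFAULT
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise MechanismError("times and signal must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise MechanismError("times must be strictly increasing")


@dataclass(frozen=True)
class AmplitudeMap:
    """Linear observable model: signal = baseline + sum a_s * [s](t)."""

    coefficients: Mapping[str, float]
    baseline: float = 0.0


@dataclass
class SimulationResult:
    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    signal: np.ndarray | None = None

    def conservation_error(self, scheme: KineticScheme) -> float:
        """Worst relative drift of any conserved moiety over the trajectory."""
        worst = 0.0
        for _, members in scheme.moieties.items():
            tot = sum(self.concentrations[s] for s in members)
            if tot[0] <= 0:
                continue
            worst = max(worst, float(np.max(np.abs(tot - tot[0])) / tot[0]))
        return worst


def signal_from_trajectories(
    result: SimulationResult, amplitudes: AmplitudeMap
) -> np.ndarray:
    sig = np.full_like(result.times, float(amplitudes.baseline))
    for sp, coeff in amplitudes.coefficients.items():
        sig = sig + coeff * result.concentrations[sp]
    return sig


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _rhs_factory(scheme: KineticScheme):
    index = {s: i for i, s in enumerate(scheme.species)}
    terms = []
    for rxn in scheme.reactions:
        k = scheme.rates[rxn.rate_name]
        if k == 0.0:
            continue
        ridx = tuple(index[s] for s in rxn.reactants)
        pidx = tuple(index[s] for s in rxn.products)
        terms.append((k, ridx, pidx))

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for k, ridx, pidx in terms:
            flux = k
            for i in ridx:
                flux *= y[i]
            for i in ridx:
                dy[i] -= flux
            for i in pidx:
                dy[i] += flux
        return dy

    return rhs


def simulate(
    scheme: KineticScheme,
    initial_concentrations: Mapping[str, float],
    times: np.ndarray,
    amplitudes: AmplitudeMap | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    check_conservation: bool = True,
    t_start: float | None = None,
) -> SimulationResult:
    """Integrate the mass-action ODEs with a stiff solver (LSODA).

    Rate constants in such schemes span several orders of magnitude, so a
    stiff method with tight tolerances (rtol 1e-8) is used.  Conservation of
    every declared moiety is asserted to 1e-6 relative unless disabled.

    ``t_start`` is the instant the initial concentrations apply (the mixing
    time); it defaults to ``times[0]``.  Pass ``t_start=0.0`` when the first
    observed point sits after an instrument dead time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise MechanismError("times must be a strictly increasing 1-D array")
    if t_start is None:
        t_start = float(times[0])
    if t_start > times[0]:
        raise MechanismError("t_start must not exceed the first output time")
    y0 = np.zeros(len(scheme.species))
    index = {s: i for i, s in enumerate(scheme.species)}
    for sp, c in initial_concentrations.items():
        if sp not in index:
            raise MechanismError(f"unknown species {sp!r} in initial concentrations")
        if c < 0:
            raise MechanismError(f"negative initial concentration for {sp!r}")
        y0[index[sp]] = c

    sol = solve_ivp(
        _rhs_factory(scheme),
        (t_start, times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    conc = {s: sol.y[index[s]] for s in scheme.species}
    result = SimulationResult(times=times, concentrations=conc)
    if check_conservation:
        err = result.conservation_error(scheme)
        if err > 1e-6:
            raise RuntimeError(f"mass conservation violated: relative drift {err:.2e}")
    if amplitudes is not None:
        result.signal = signal_from_trajectories(result, amplitudes)
    return result


def dead_time_mask(
    trace: FluorescenceTrace,
    dead_time: float | None = None,
    artifact: FluorescenceTrace | None = None,
) -> FluorescenceTrace:
    """Drop points before the instrument dead time; optionally subtract a
    measured mixing-artifact baseline trace (interpolated onto the grid)."""
    dt = trace.dead_time if dead_time is None else dead_time
    if dt < 0:
        raise MechanismError("dead_time must be >= 0")
    keep = trace.times >= dt
    if not np.any(keep):
        raise MechanismError("dead time exceeds the trace span")
    sig = trace.signal[keep]
    if artifact is not None:
        sig = sig - np.interp(trace.times[keep], artifact.times, artifact.signal)
    return FluorescenceTrace(
        times=trace.times[keep],
        signal=sig,
        dNTP_concentration=trace.dNTP_concentration,
        dead_time=dt,
        label=trace.label,
    )


# ---------------------------------------------------------------------------
# multi-exponential (trap) fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrapFit:
    """Triple-exponential description of the reverse-rate trap experiment.

    ``rates`` are sorted descending.  ``assignment`` maps them to mechanism
    steps in reverse-pathway order: the fastest phase to the reverse of the
    second non-covalent step (k_m4), the middle to fingers re-opening
    (k_m3), the slowest to dNTP release (governed by the binding
    equilibrium).  ``ambiguous`` flags near-equal rates where this ordering
    is not meaningful.
    """

    rates: tuple[float, ...]
    amplitudes: tuple[float, ...]
    offset: float
    n_selected: int
    aic: dict[int, float]
    assignment: dict[str, float]
    ambiguous: bool


def _multi_exp_model(t, offset, *params):
    out = np.full_like(t, offset, dtype=float)
    for i in range(0, len(params), 2):
        out = out + params[i] * np.exp(-params[i + 1] * t)
    return out


def fit_multi_exponential(
    trace: FluorescenceTrace, n_components: int, *, n_starts: int = 8, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Fit offset + sum_i a_i exp(-k_i t); returns (params, rss)."""
    t = trace.times - trace.times[0]
    y = trace.signal
    if len(t) < 2 * n_components + 2:
        raise FitFailure("too few points for the requested exponential count")
    if np.allclose(y, y[0]):
        raise FitFailure("constant trace: no decay to fit")
    rng = np.random.default_rng(seed)
    span = t[-1] if t[-1] > 0 else 1.0
    amp_scale = float(np.ptp(y)) or 1.0
    best = None
    for _ in range(n_starts):
        ks = np.sort(np.exp(rng.uniform(np.log(0.3 / span), np.log(300.0 / span), n_components)))[::-1]
        p0 = [float(y[-1])]
        for k in ks:
            p0 += [amp_scale / n_components, float(k)]
        lb = [-np.inf] + [-np.inf, 1e-9] * n_components
        ub = [np.inf] + [np.inf, np.inf] * n_components
        try:
            popt, _ = curve_fit(_multi_exp_model, t, y, p0=p0, bounds=(lb, ub), maxfev=40000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_multi_exp_model(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailure(f"{n_components}-exponential fit did not converge")
    return best


def fit_triple_exponential(
    trace: FluorescenceTrace, *, seed: int = 0, ambiguity_ratio: float = 1.5
) -> TrapFit:
    """Fit 1-, 2- and 3-exponential models and select by AIC.

    Designed for the trap experiment: a pre-formed closed ternary complex is
    mixed with excess unlabeled trap, so the observed relaxation is a sum of
    decaying exponentials whose rates report the reverse conformational
    steps.  Rates are reported sorted descending and assigned to (k_m4,
    k_m3, dNTP release) in that order; if adjacent rates differ by less
    than ``ambiguity_ratio`` the assignment is flagged ambiguous.
    """
    aic: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, float]] = {}
    n_pts = len(trace.times)
    if n_pts < 12:
        raise MechanismError("trap fit needs >= 12 points after the dead time")
    for n in (1, 2, 3):
        try:
            popt, rss = fit_multi_exponential(trace, n, seed=seed + n)
        except FitFailure:
            continue
        k_params = 1 + 2 * n
        aic[n] = n_pts * math.log(max(rss, 1e-300) / n_pts) + 2 * k_params
        fits[n] = (popt, rss)
    if not fits:
        raise FitFailure("no exponential model converged on this trace")
    n_sel = min(aic, key=aic.get)
    popt3, _ = fits.get(3, fits[max(fits)])
    offset = float(popt3[0])
    pairs = sorted(
        ((float(popt3[i + 1]), float(popt3[i])) for i in range(1, len(popt3), 2)),
        reverse=True,
    )
    rates = tuple(k for k, _ in pairs)
    amps = tuple(a for _, a in pairs)
    names = ("k_m4", "k_m3", "dNTP_release")
    assignment = {name: k for name, k in zip(names, rates)}
    ambiguous = any(
        rates[i] / rates[i + 1] < ambiguity_ratio for i in range(len(rates) - 1)
    )
    return TrapFit(
        rates=rates,
        amplitudes=amps,
        offset=offset,
        n_selected=n_sel,
        aic=aic,
        assignment=assignment,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# constrained global fitting
# ---------------------------------------------------------------------------


@dataclass
class GlobalFitResult:
    rates: dict[str, float]
    free_names: tuple[str, ...]
    amplitudes: list[AmplitudeMap]
    residual_norm: float
    covariance: np.ndarray | None
    stderr: dict[str, float]
    ill_conditioned: bool


def _solve_amplitudes(
    result: SimulationResult, y: np.ndarray, observed_species: Sequence[str]
) -> tuple[AmplitudeMap, np.ndarray]:
    """Best linear amplitudes + baseline for one trace (ordinary lstsq)."""
    cols = [result.concentrations[s] for s in observed_species]
    A = np.column_stack([*cols, np.ones_like(y)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    amap = AmplitudeMap(
        coefficients={s: float(c) for s, c in zip(observed_species, coef[:-1])},
        baseline=float(coef[-1]),
    )
    return amap, y - fitted


def fit_global(
    traces: Sequence[FluorescenceTrace],
    scheme: KineticScheme,
    initial_concentrations: Mapping[str, float],
    *,
    free_rates: Sequence[str] = ("k_p3", "k_p4"),
    observed_species: Sequence[str] = ("EDN", "EcDN", "EccDN", "EDp"),
    apply_dead_time: bool = True,
) -> GlobalFitResult:
    """Globally fit shared rate constants across a [dNTP] series of traces.

    Constrained rates (``scheme.constraints``) never move.  The free rates
    are optimized in log space (they are positive and poorly scaled
    otherwise); at each iteration every trace is simulated with its own
    dNTP concentration added to ``initial_concentrations`` and its
    amplitudes + baseline are profiled out by linear least squares.

    Degenerate case: with no free rates the fit reduces to the per-trace
    amplitude solve.
    """
    for name in free_rates:
        if name in scheme.constraints:
            raise MechanismError(f"rate {name!r} is constrained; cannot free it")
        if name not in scheme.rates:
            raise MechanismError(f"unknown free rate {name!r}")
    if not traces:
        raise MechanismError("need at least one trace")
    prepared = [dead_time_mask(tr) if apply_dead_time else tr for tr in traces]

    def residuals_for(rates_log: np.ndarray):
        sch = scheme.with_rates(
            **{n: float(10.0**v) for n, v in zip(free_rates, rates_log)}
        )
        res_blocks = []
        amaps = []
        for tr in prepared:
            init = dict(initial_concentrations)
            init["N"] = init.get("N", 0.0) + tr.dNTP_concentration
            # mixing happens at t = 0; the first usable point sits after the
            # dead time, so the trajectory must still start at zero
            sim = simulate(sch, init, tr.times, check_conservation=False, t_start=0.0)
            amap, resid = _solve_amplitudes(sim, tr.signal, observed_species)
            amaps.append(amap)
            res_blocks.append(resid)
        return np.concatenate(res_blocks), amaps

    if not free_rates:
        resid, amaps = residuals_for(np.empty(0))
        return GlobalFitResult(
            rates=dict(scheme.rates),
            free_names=(),
            amplitudes=amaps,
            residual_norm=float(np.linalg.norm(resid)),
            covariance=None,
            stderr={},
            ill_conditioned=False,
        )

    x0 = np.log10([scheme.rates[n] if scheme.rates[n] > 0 else 1.0 for n in free_rates])
    sol = least_squares(
        lambda x: residuals_for(x)[0], x0, method="lm", xtol=1e-12, ftol=1e-12
    )
    if not sol.success:
        raise FitFailure(f"global fit did not converge: {sol.message}")
    resid, amaps = residuals_for(sol.x)
    fitted = {n: float(10.0**v) for n, v in zip(free_rates, sol.x)}

    # covariance in log10 space via J^T J; singular => unidentifiable set
    J = sol.jac
    dof = max(len(resid) - len(free_rates), 1)
    s2 = float(resid @ resid) / dof
    ill = False
    cov = None
    stderr: dict[str, float] = {}
    try:
        JTJ = J.T @ J
        cond = np.linalg.cond(JTJ)
        ill = not np.isfinite(cond) or cond > 1e12
        cov = s2 * np.linalg.inv(JTJ)
        stderr = {
            n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(free_rates)
        }
    except np.linalg.LinAlgError:
        ill = True
    return GlobalFitResult(
        rates={**scheme.rates, **fitted},
        free_names=tuple(free_rates),
        amplitudes=amaps,
        residual_norm=float(np.linalg.norm(resid)),
        covariance=cov,
        stderr=stderr,
        ill_conditioned=ill,
    )
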