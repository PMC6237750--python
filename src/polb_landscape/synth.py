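"""Seeded synthetic-data generators for every pipeline input.

Raw spectra and stopped-flow records for this system live in instrument
archives; the generators here produce statistically matched stand-ins so
every analysis stage is testable from a clean checkout:

* methyl peak lists: a fixed "open" reference, a "closed" reference
  displaced from it, and a test state interpolated a fraction ``f`` of the
  way from open to closed, with optional orthogonal (off-pathway)
  perturbations and Gaussian peak-position noise;
* chemical-quench progress curves and k_obs-vs-[dNTP] saturation series
  from the burst / single-exponential / hyperbolic models;
* stopped-flow fluorescence traces from the mass-action scheme (including
  the trap configuration), with additive Gaussian noise and the 2 ms
  instrument dead time;
* CPMG dispersion panels mixing flat and dispersive residues;
* donor-emission / acceptor-extinction spectrum pairs (Gaussian bands, or
  rectangular bands with an analytic overlap for oracle checks).

All randomness flows from ``LandscapeScenario.seed``; identical scenarios
produce identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import mechanism
from .cpmg import DispersionCurve, r2_model
from .fret import Spectrum
from .kinetics import ProgressCurve, burst_model
from .mechanism import (
    AmplitudeMap,
    FluorescenceTrace,
    KineticScheme,
    dead_time_mask,
    default_scheme,
    simulate,
)
from .shiftvec import CARBON_SCALE, MethylPeak, MethylPeakList

__all__ = [
    "LandscapeScenario",
    "gen_peak_lists",
    "gen_progress_curves",
    "gen_saturation_series",
    "gen_stopped_flow",
    "gen_trap_trace",
    "gen_cpmg",
    "gen_spectra",
]

ILV_TYPES = ("I", "L", "V")


@dataclass
class LandscapeScenario:
    """One reproducible study condition for all generators.

    Defaults mirror the wild-type template-G study conditions: burst
    parameters (100 nM amplitude, 9 1/s burst, 1.2 1/s steady state),
    saturation parameters (k_pol 12.0 1/s, K_d 1.5 uM) over the 0.5-1500 uM
    titration range, the wild-type scheme rates for stopped flow, a CPMG
    panel of 26 flat + 14 dispersive residues, and a 490 nm donor band.
    """

    seed: int = 0

    # --- peak lists ---
    n_peaks: int = 40
    closure_fraction: float = 0.5
    off_pathway_keys: tuple[tuple[int, str], ...] = ()
    off_pathway_magnitude: float = 0.08  # ppm, scaled-plane length
    sigma_H: float = 0.0  # ppm
    sigma_C: float = 0.0  # ppm
    # reference open->closed displacement lengths in the scaled plane (ppm)
    ref_magnitude_range: tuple[float, float] = (0.12, 0.45)

    # --- kinetics ---
    burst_E_app: float = 100.0  # nM
    burst_k_obs: float = 9.0  # 1/s
    burst_k_ss: float = 1.2  # 1/s
    k_pol: float = 12.0  # 1/s
    K_d_dNTP: float = 1.5  # uM
    titration_range: tuple[float, float] = (0.5, 1500.0)  # uM
    n_titration: int = 10
    curve_noise_fraction: float = 0.0  # of amplitude

    # --- stopped flow ---
    enzyme: str = "WT"
    sf_enzyme_conc: float = 0.25  # uM post-mix (500 nM pre-mix)
    sf_dna_conc: float = 0.1  # uM post-mix (200 nM pre-mix)
    sf_dntp_concs: tuple[float, ...] = (1.0, 5.0, 20.0, 100.0)  # uM
    sf_noise: float = 0.0  # a.u.
    dead_time: float = mechanism.DEAD_TIME_DEFAULT
    trap_rates: tuple[float, float, float] = (163.0, 48.2, 5.0)  # 1/s

    # --- CPMG ---
    n_flat: int = 26
    n_dispersive: int = 14
    cpmg_noise: float = 0.2  # 1/s
    cpmg_R2_0_range: tuple[float, float] = (12.0, 20.0)
    cpmg_Rex_range: tuple[float, float] = (3.0, 8.0)
    cpmg_kex_range: tuple[float, float] = (800.0, 2500.0)
    nu_cpmg_grid: tuple[float, ...] = (25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 600.0, 800.0, 1000.0)

    # --- spectra ---
    donor_peak_nm: float = 490.0
    donor_width_nm: float = 35.0
    acceptor_peak_nm: float = 475.0
    acceptor_width_nm: float = 45.0
    acceptor_eps_max: float = 3.2e4  # M^-1 cm^-1

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for one named output stream."""
        # crc32 rather than hash(): stable across processes
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------


def _reference_peaks(scenario: LandscapeScenario):
    """Deterministic open/closed reference peak positions for the scenario."""
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, 1904])
    )
    residues = np.sort(
        rng.choice(np.arange(2, 336), size=scenario.n_peaks, replace=False)
    )
    entries = []
    for res in residues:
        rtype = ILV_TYPES[int(rng.integers(0, 3))]
        methyl = {"I": "CD1", "L": "CD1", "V": "CG1"}[rtype]
        dH = float(rng.uniform(0.0, 1.5))
        dC = float(rng.uniform(9.0, 27.0))
        # open->closed displacement: random direction, controlled scaled length
        ang = float(rng.uniform(0.0, 2.0 * np.pi))
        mag = float(rng.uniform(*scenario.ref_magnitude_range))
        ref_H = mag * np.cos(ang)
        ref_C = mag * np.sin(ang) / CARBON_SCALE
        entries.append((int(res), rtype, methyl, dH, dC, ref_H, ref_C))
    return entries


def gen_peak_lists(
    scenario: LandscapeScenario,
) -> tuple[MethylPeakList, MethylPeakList, MethylPeakList]:
    """(open_ref, closed_ref, test) methyl peak lists.

    Test peaks sit at ``open + f*(closed - open)``; members of
    ``off_pathway_keys`` are instead displaced perpendicular to the
    reference vector in the carbon-scaled plane (so their intended class is
    known by construction).  Gaussian noise sigma_H/sigma_C is then added
    to the test positions.
    """
    f = scenario.closure_fraction
    if not (0.0 <= f <= 1.0):
        raise ValueError("closure_fraction must lie in [0, 1]")
    rng = scenario.rng("peaks")
    off = set(scenario.off_pathway_keys)
    open_peaks, closed_peaks, test_peaks = [], [], []
    for res, rtype, methyl, dH, dC, ref_H, ref_C in _reference_peaks(scenario):
        open_peaks.append(MethylPeak(res, rtype, methyl, dH, dC))
        closed_peaks.append(MethylPeak(res, rtype, methyl, dH + ref_H, dC + ref_C))
        if (res, methyl) in off:
            # rotate the scaled reference vector by 90 degrees, rescale
            sh, sc = ref_H, CARBON_SCALE * ref_C
            norm = np.hypot(sh, sc)
            scale = scenario.off_pathway_magnitude / norm
            th, tc = -sc * scale, sh * scale / CARBON_SCALE
        else:
            th, tc = f * ref_H, f * ref_C
        nh = float(rng.normal(0.0, scenario.sigma_H)) if scenario.sigma_H else 0.0
        nc = float(rng.normal(0.0, scenario.sigma_C)) if scenario.sigma_C else 0.0
        test_peaks.append(MethylPeak(res, rtype, methyl, dH + th + nh, dC + tc + nc))
    return (
        MethylPeakList("open_ref", open_peaks),
        MethylPeakList("closed_ref", closed_peaks),
        MethylPeakList("test", test_peaks),
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def gen_progress_curves(
    scenario: LandscapeScenario,
    *,
    kind: str = "burst",
    times: np.ndarray | None = None,
) -> ProgressCurve:
    """One synthetic chemical-quench progress curve (``burst`` or
    ``single_exponential``)."""
    rng = scenario.rng(f"curve-{kind}")
    if times is None:
        times = np.geomspace(0.02, 3.0, 30)
    times = np.asarray(times, dtype=float)
    if kind == "burst":
        y = burst_model(times, scenario.burst_E_app, scenario.burst_k_obs, scenario.burst_k_ss)
        label = "burst"
    elif kind == "single_exponential":
        y = scenario.burst_E_app * (1.0 - np.exp(-scenario.k_pol * times))
        label = "single_turnover"
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    if scenario.curve_noise_fraction:
        y = y + rng.normal(0.0, scenario.curve_noise_fraction * scenario.burst_E_app, y.shape)
    return ProgressCurve(times=times, product=y, label=label)


def gen_saturation_series(
    scenario: LandscapeScenario,
) -> list[tuple[float, float]]:
    """(concentration uM, k_obs 1/s) pairs from the hyperbolic law over the
    titration range, with fractional Gaussian noise on k_obs."""
    rng = scenario.rng("saturation")
    concs = np.geomspace(*scenario.titration_range, scenario.n_titration)
    kobs = scenario.k_pol * concs / (scenario.K_d_dNTP + concs)
    if scenario.curve_noise_fraction:
        kobs = kobs * (1.0 + rng.normal(0.0, scenario.curve_noise_fraction, kobs.shape))
    return [(float(c), float(k)) for c, k in zip(concs, kobs)]


# ---------------------------------------------------------------------------
# stopped flow
# ---------------------------------------------------------------------------

#: Donor quenching deepens along the closure pathway: open ternary partially
#: quenched, closed and post-step states more so, product complex recovering.
DEFAULT_AMPLITUDES = AmplitudeMap(
    coefficients={"EDN": -1.0, "EcDN": -3.5, "EccDN": -4.5, "EDp": -0.5},
    baseline=2.0,
)


def gen_stopped_flow(
    scenario: LandscapeScenario,
    *,
    scheme: KineticScheme | None = None,
    amplitudes: AmplitudeMap = DEFAULT_AMPLITUDES,
    times: np.ndarray | None = None,
) -> list[FluorescenceTrace]:
    """Stopped-flow FRET traces at each scenario dNTP concentration.

    Enzyme and DNA are pre-equilibrated (binary complex formed) and dNTP is
    added at t = 0; traces carry Gaussian noise and are truncated at the
    instrument dead time.
    """
    sch = scheme if scheme is not None else default_scheme(scenario.enzyme)
    rng = scenario.rng("stopped-flow")
    if times is None:
        times = np.linspace(0.0, 0.5, 501)
    traces = []
    for n_conc in scenario.sf_dntp_concs:
        init = {
            # pre-incubated binary complex: essentially all DNA bound
            "ED": scenario.sf_dna_conc,
            "E": scenario.sf_enzyme_conc - scenario.sf_dna_conc,
            "N": n_conc,
        }
        sim = simulate(sch, init, times, amplitudes=amplitudes)
        sig = sim.signal
        if scenario.sf_noise:
            sig = sig + rng.normal(0.0, scenario.sf_noise, sig.shape)
        tr = FluorescenceTrace(
            times=times,
            signal=sig,
            dNTP_concentration=n_conc,
            dead_time=scenario.dead_time,
            label=f"dNTP_{n_conc:g}uM",
        )
        traces.append(dead_time_mask(tr))
    return traces


def gen_trap_trace(
    scenario: LandscapeScenario,
    *,
    times: np.ndarray | None = None,
    amplitudes: tuple[float, float, float] = (1.2, 0.9, 0.4),
    offset: float = 1.5,
) -> FluorescenceTrace:
    """Trap-experiment relaxation: a pre-formed closed ternary complex mixed
    with excess unlabeled trap so released dNTP never rebinds.

    The observable is modeled directly as the triple-exponential relaxation
    with the scenario's reverse-step rates (fastest: reverse of the second
    non-covalent step; middle: fingers re-opening; slowest: dNTP release).
    """
    rng = scenario.rng("trap")
    if times is None:
        times = np.linspace(0.0, 1.2, 600)
    times = np.asarray(times, dtype=float)
    sig = np.full_like(times, offset)
    for a, k in zip(amplitudes, scenario.trap_rates):
        sig = sig + a * np.exp(-k * times)
    if scenario.sf_noise:
        sig = sig + rng.normal(0.0, scenario.sf_noise, sig.shape)
    tr = FluorescenceTrace(
        times=times, signal=sig, dead_time=scenario.dead_time, label="trap"
    )
    return dead_time_mask(tr)


# ---------------------------------------------------------------------------
# CPMG
# ---------------------------------------------------------------------------


def gen_cpmg(
    scenario: LandscapeScenario,
) -> tuple[list[DispersionCurve], list[bool]]:
    """A panel of dispersion curves plus ground-truth dispersive labels."""
    rng = scenario.rng("cpmg")
    inv_tau = 2.0 * np.asarray(scenario.nu_cpmg_grid, dtype=float)
    curves: list[DispersionCurve] = []
    labels: list[bool] = []
    total = scenario.n_flat + scenario.n_dispersive
    dispersive_idx = set(
        rng.choice(total, size=scenario.n_dispersive, replace=False).tolist()
    )
    for i in range(total):
        r20 = float(rng.uniform(*scenario.cpmg_R2_0_range))
        if i in dispersive_idx:
            rex = float(rng.uniform(*scenario.cpmg_Rex_range))
            kex = float(rng.uniform(*scenario.cpmg_kex_range))
            y = r2_model(inv_tau, r20, rex, kex)
            labels.append(True)
        else:
            y = np.full_like(inv_tau, r20)
            labels.append(False)
        if scenario.cpmg_noise:
            y = y + rng.normal(0.0, scenario.cpmg_noise, y.shape)
        curves.append(
            DispersionCurve(
                residue_key=f"res{i + 1}",
                tau_cp_inverse=inv_tau,
                R2_eff=y,
                uncertainties=np.full_like(inv_tau, scenario.cpmg_noise) if scenario.cpmg_noise else None,
            )
        )
    return curves, labels


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def gen_spectra(
    scenario: LandscapeScenario,
    *,
    mode: str = "gaussian",
    grid_nm: np.ndarray | None = None,
    rect_donor: tuple[float, float] = (490.0, 500.0),
    rect_acceptor_eps: float = 1.0e4,
) -> tuple[Spectrum, Spectrum]:
    """(donor emission, acceptor extinction) spectra.

    ``mode="gaussian"`` gives realistic overlapping bands (donor peak at
    490 nm by default).  ``mode="rectangular"`` gives a unit-area donor
    rectangle on ``rect_donor`` and a constant acceptor extinction, for
    which the overlap integral has a polynomial closed form.
    """
    if grid_nm is None:
        grid_nm = np.linspace(400.0, 650.0, 1001)
    grid_nm = np.asarray(grid_nm, dtype=float)
    if mode == "gaussian":
        donor = np.exp(-0.5 * ((grid_nm - scenario.donor_peak_nm) / scenario.donor_width_nm) ** 2)
        acceptor = scenario.acceptor_eps_max * np.exp(
            -0.5 * ((grid_nm - scenario.acceptor_peak_nm) / scenario.acceptor_width_nm) ** 2
        )
    elif mode == "rectangular":
        lo, hi = rect_donor
        donor = np.where((grid_nm >= lo) & (grid_nm <= hi), 1.0 / (hi - lo), 0.0)
        acceptor = np.full_like(grid_nm, rect_acceptor_eps)
    else:
        raise ValueError(f"unknown spectra mode {mode!r}")
    return (
        Spectrum(grid_nm, donor, "emission"),
        Spectrum(grid_nm, acceptor, "extinction"),
    )
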