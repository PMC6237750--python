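"""Mass-action simulation, constrained global fitting and the trap fit."""

import numpy as np
import pytest

from polb_landscape.kinetics import FitFailure
from polb_landscape.mechanism import (
    AmplitudeMap,
    FluorescenceTrace,
    KineticScheme,
    MechanismError,
    Reaction,
    dead_time_mask,
    default_scheme,
    fit_global,
    fit_triple_exponential,
    simulate,
)
from polb_landscape.synth import (
    DEFAULT_AMPLITUDES,
    LandscapeScenario,
    gen_stopped_flow,
    gen_trap_trace,
)


def two_state_scheme(k_fwd=124.0, k_rev=11.5):
    return KineticScheme(
        species=("EDN", "EcDN"),
        reactions=(
            Reaction(("EDN",), ("EcDN",), "k_p3"),
            Reaction(("EcDN",), ("EDN",), "k_m3"),
        ),
        rates={"k_p3": k_fwd, "k_m3": k_rev},
        moieties={"enzyme": ("EDN", "EcDN")},
    )


class TestSimulate:
    def test_two_state_relaxation_closed_form(self):
        """Isolated closing step relaxes at k_p3 + k_m3 = 135.5 1/s to the
        equilibrium closed fraction 124/135.5."""
        t = np.linspace(0.0, 0.25, 400)
        sim = simulate(two_state_scheme(), {"EDN": 1.0}, t)
        k = 124.0 + 11.5
        expected = (124.0 / k) * (1.0 - np.exp(-k * t))
        closed = sim.concentrations["EcDN"]
        rel = np.abs(closed[1:] - expected[1:]) / expected[1:]
        assert np.max(rel) < 1e-5
        assert closed[-1] == pytest.approx(124.0 / 135.5, rel=1e-6)

    def test_mass_conservation(self):
        scheme = default_scheme("WT")
        t = np.linspace(0.0, 2.0, 300)
        sim = simulate(scheme, {"ED": 0.1, "E": 0.15, "N": 50.0}, t)
        assert sim.conservation_error(scheme) < 1e-6

    def test_detailed_balance_of_binding_step(self):
        """Equilibrium [EDN]/([ED][N]) equals k_p2/k_m2 for isolated binding."""
        scheme = KineticScheme(
            species=("ED", "N", "EDN"),
            reactions=(
                Reaction(("ED", "N"), ("EDN",), "k_p2"),
                Reaction(("EDN",), ("ED", "N"), "k_m2"),
            ),
            rates={"k_p2": 100.0, "k_m2": 150.0},
            moieties={"enzyme": ("ED", "EDN")},
        )
        t = np.linspace(0.0, 5.0, 100)
        sim = simulate(scheme, {"ED": 0.1, "N": 10.0}, t)
        q = sim.concentrations["EDN"][-1] / (
            sim.concentrations["ED"][-1] * sim.concentrations["N"][-1]
        )
        assert q == pytest.approx(100.0 / 150.0, rel=1e-4)

    def test_equal_amplitudes_give_constant_signal(self):
        """With every enzyme species weighted equally and baseline 0, the
        signal is coefficient x total enzyme at all times (conservation)."""
        scheme = default_scheme("WT")
        amp = AmplitudeMap(
            coefficients={s: 2.0 for s in ("E", "ED", "EDN", "EcDN", "EccDN", "EDp")},
            baseline=0.0,
        )
        t = np.linspace(0.0, 1.0, 100)
        sim = simulate(scheme, {"ED": 0.1, "E": 0.15, "N": 20.0}, t, amplitudes=amp)
        assert np.allclose(sim.signal, 2.0 * 0.25, rtol=1e-6)

    def test_zero_dntp_never_populates_ternary(self):
        scheme = default_scheme("WT")
        t = np.linspace(0.0, 1.0, 50)
        sim = simulate(scheme, {"ED": 0.1, "E": 0.15}, t)
        for sp in ("EDN", "EcDN", "EccDN"):
            assert np.max(np.abs(sim.concentrations[sp])) < 1e-15

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(MechanismError):
            simulate(two_state_scheme(), {"EDN": -1.0}, np.linspace(0, 1, 10))


class TestDeadTime:
    def _trace(self):
        t = np.arange(0.0, 0.02, 0.001)
        return FluorescenceTrace(times=t, signal=np.ones_like(t), dead_time=0.0)

    def test_zero_dead_time_is_identity(self):
        tr = self._trace()
        out = dead_time_mask(tr, 0.0)
        assert np.array_equal(out.times, tr.times)

    def test_two_millisecond_mask_drops_first_points(self):
        out = dead_time_mask(self._trace(), 0.002)
        assert out.times[0] == pytest.approx(0.002)
        assert len(out.times) == 18

    def test_dead_time_beyond_span_rejected(self):
        with pytest.raises(MechanismError):
            dead_time_mask(self._trace(), 1.0)

    def test_artifact_subtraction(self):
        tr = self._trace()
        artifact = FluorescenceTrace(times=tr.times, signal=np.full_like(tr.times, 0.25))
        out = dead_time_mask(tr, 0.0, artifact=artifact)
        assert np.allclose(out.signal, 0.75)


class TestGlobalFit:
    def test_noise_free_recovery_of_free_rates(self):
        """Constrained fit recovers (k_p3, k_p4) to <1% from clean traces."""
        sc = LandscapeScenario(seed=2)
        traces = gen_stopped_flow(sc)
        start = default_scheme("WT").with_rates(k_p3=80.0, k_p4=25.0)
        res = fit_global(
            traces, start, {"ED": sc.sf_dna_conc, "E": sc.sf_enzyme_conc - sc.sf_dna_conc}
        )
        assert res.rates["k_p3"] == pytest.approx(124.0, rel=0.01)
        assert res.rates["k_p4"] == pytest.approx(40.0, rel=0.01)

    def test_constrained_rate_cannot_be_freed(self):
        scheme = default_scheme("WT")
        with pytest.raises(MechanismError):
            fit_global([], scheme, {}, free_rates=("k_m3",))

    def test_all_rates_fixed_degenerates_to_amplitude_solve(self):
        sc = LandscapeScenario(seed=2, sf_dntp_concs=(20.0,))
        traces = gen_stopped_flow(sc)
        res = fit_global(
            traces,
            default_scheme("WT"),
            {"ED": sc.sf_dna_conc, "E": sc.sf_enzyme_conc - sc.sf_dna_conc},
            free_rates=(),
        )
        assert res.free_names == ()
        # generating amplitudes are linear in species, so residual ~ 0
        assert res.residual_norm < 1e-7
        amap = res.amplitudes[0]
        assert amap.coefficients["EcDN"] == pytest.approx(-3.5, abs=1e-4)


class TestTrapFit:
    def test_recovers_generating_rates(self):
        """Triple-exponential fit recovers (163, 48.2, 5) within 5%."""
        fit = fit_triple_exponential(gen_trap_trace(LandscapeScenario(seed=3)), seed=1)
        assert fit.n_selected == 3
        for got, want in zip(fit.rates, (163.0, 48.2, 5.0)):
            assert got == pytest.approx(want, rel=0.05)
        assert fit.assignment["k_m4"] == pytest.approx(163.0, rel=0.05)
        assert fit.assignment["k_m3"] == pytest.approx(48.2, rel=0.05)
        assert not fit.ambiguous

    def test_model_selection_prefers_two_for_biexponential_data(self):
        t = np.linspace(0.0, 1.0, 300)
        rng = np.random.default_rng(5)
        sig = 1.0 + 0.8 * np.exp(-50.0 * t) + 0.5 * np.exp(-4.0 * t)
        sig = sig + rng.normal(0, 0.003, t.shape)
        tr = FluorescenceTrace(times=t, signal=sig, dead_time=0.0)
        fit = fit_triple_exponential(tr, seed=2)
        assert fit.n_selected == 2

    def test_constant_trace_fails(self):
        t = np.linspace(0.0, 1.0, 50)
        tr = FluorescenceTrace(times=t, signal=np.ones_like(t), dead_time=0.0)
        with pytest.raises(FitFailure):
            fit_triple_exponential(tr)
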