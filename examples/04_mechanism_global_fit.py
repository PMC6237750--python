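"""Fit the precatalytic kinetic scheme to a stopped-flow dNTP series.

Simulates clean traces from the wild-type rate set, then recovers the two
free conformational rates (fingers closing k_p3 and the second non-covalent
step k_p4) by constrained global fitting, and fits the trap experiment for
the reverse rates.
"""

from polb_landscape.mechanism import default_scheme, fit_global, fit_triple_exponential
from polb_landscape.synth import LandscapeScenario, gen_stopped_flow, gen_trap_trace

scenario = LandscapeScenario(seed=7)
traces = gen_stopped_flow(scenario)
print(f"{len(traces)} traces at [dNTP] = "
      f"{[tr.dNTP_concentration for tr in traces]} uM, 2 ms dead time")

start = default_scheme("WT").with_rates(k_p3=60.0, k_p4=15.0)  # wrong starts
result = fit_global(
    traces, start,
    {"ED": scenario.sf_dna_conc, "E": scenario.sf_enzyme_conc - scenario.sf_dna_conc},
)
print(f"fingers closing  k_p3 = {result.rates['k_p3']:7.2f} 1/s")
print(f"second step      k_p4 = {result.rates['k_p4']:7.2f} 1/s")
print(f"residual norm = {result.residual_norm:.2e}; "
      f"constrained rates (binding, chemistry, reverses) never moved")

trap = fit_triple_exponential(gen_trap_trace(scenario), seed=7)
print(f"trap experiment ({trap.n_selected}-exponential preferred): "
      f"rates = {[f'{k:.1f}' for k in trap.rates]} 1/s")
print(f"  assigned: reverse second step {trap.assignment['k_m4']:.1f}, "
      f"fingers opening {trap.assignment['k_m3']:.1f} 1/s")
print()
print("The forward conformational rates come from the dNTP series; the")
print("reverse rates are measured independently by trapping released dNTP.")
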