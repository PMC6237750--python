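"""Build the nucleotide-incorporation fidelity table for two enzymes.

Inputs are the measured single-turnover constants (k_pol in 1/s, K_d in
uM) for correct and incorrect incorporation on templates G and T.
"""

from polb_landscape.kinetics import FidelityTable

table = FidelityTable.from_measurements(
    [
        # template, enzyme, (k_pol, K_d) correct, (k_pol, K_d) incorrect
        ("G", "WT", (12.0, 1.5), (0.134, 365.0)),
        ("G", "I260Q", (3.6, 0.6), (0.095, 16.0)),
        ("T", "WT", (12.2, 5.8), (0.14, 427.0)),
        ("T", "I260Q", (5.5, 1.9), (0.09, 11.5)),
    ],
    rounding="none",
)

for r in table.rows:
    fold = f", {r.x_fold:.1f}-fold below WT" if r.x_fold else ""
    print(
        f"template {r.template_base} {r.enzyme:6s}: "
        f"eff(correct) {r.efficiency_correct:8.3g} /uM/s, "
        f"eff(incorrect) {r.efficiency_incorrect:8.3g} /uM/s, "
        f"fidelity {r.fidelity:8.0f}{fold}"
    )
print()
print("Fidelity = (correct + incorrect efficiency)/incorrect efficiency:")
print("the mutator variant loses ~21x (template G) and ~17x (template T),")
print("driven mostly by tighter binding of the wrong nucleotide (lower K_d).")
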