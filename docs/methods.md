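# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices made
where the design was open.

## Shift-vector analysis

Each methyl peak carries two chemical shifts (¹H, ¹³C).  Two different
carbon scalings appear in the field and both are used here, each for its
own purpose: the **significance filter** uses the combined shift
√((Δδ_H² + ¼Δδ_C²)/2) against a threshold (default 0.025 ppm, strict
inequality), while **all vector geometry** (magnitude, Δδₙ, cos θ,
RMSD₁.₀) uses the scaled plane (Δδ_H, 0.2514·Δδ_C).  Mixing the two would
silently change classifications, so they are kept in separate code paths.

The threshold itself can be re-derived from replicate apo spectra with
`significance_threshold` (factor × mean per-peak combined shift over
replicate pairs; factor defaults to 1.5).  Replicate pairing is
within-group by default — replicates of the same enzyme measure
instrumental reproducibility, which is what a significance floor should
capture — with a between-group mode exposed because the alternative
reading (pairing across enzymes) is defensible.

Boundary conventions: peaks exactly at the significance threshold are
not significant ("higher than" is strict); cos θ exactly at the 0.8
cutoff is on-pathway (only values below the cutoff indicate off-pathway
motion).  Reference vectors shorter than 10⁻⁶ ppm make Δδₙ and cos θ
undefined; such peaks are reported `reference_degenerate` and excluded
from RMSD.  A fully open test state (zero experimental vector) has a
well-defined Δδₙ = 0 but no direction, so cos θ is reported as missing
rather than forced.  RMSD₁.₀ averages over significant, non-degenerate
peaks by default (`rmsd_over="all_matched"` includes everything), and the
reported mean Δδₙ / mean cos θ likewise average significant peaks only.
Non-stereospecifically assigned methyls enter as independent rows.

Subdomain boundaries (lyase 1–87, thumb 88–151, palm 152–262, fingers
263–335) are a configurable default chosen to place the catalytic
aspartates (D190/D192/D256) in the palm and I277/R283 in the fingers;
users with a different domain convention can supply their own map.
Re-referencing to an anchor resonance that is insensitive to ligand
binding (V221 here) is available as an explicit step
(`rereference`) rather than applied implicitly.

## Kinetics and fidelity

The biphasic burst model is implemented in its standard dimensionless
form, amplitude ratio squared:

    [P](t) = E_app [ (k_obs/(k_obs+k_ss))² (1 − e^{−(k_obs+k_ss)t})
                     + (k_obs k_ss/(k_obs+k_ss)) t ]

A literal `as_printed` variant (k_obs, not k_obs², in the exponential
amplitude) is provided for reproducing legacy fits; it breaks the
k_ss → 0 single-exponential limit and is not the default.

Fits are unweighted nonlinear least squares (optional 1/σ² weights) with
multi-start initialization from log-spaced rate grids, because burst and
saturation problems are prone to local minima when the two timescales are
poorly separated.  A monotone-linear curve (no burst signal, line RSS
within 1% of total variance) and a rate hitting the start-grid ceiling
both raise an explicit fit failure rather than returning an unbounded
estimate.  Saturation fits whose sampled concentrations do not bracket
the fitted K_d are flagged ill-conditioned (k_pol and K_d trade off along
a ridge there).

Fidelity arithmetic: efficiency = k_pol/K_d (μM⁻¹s⁻¹), discrimination
D_kpol = k_pol(c)/k_pol(i) and D_Kd = K_d(i)/K_d(c), fidelity =
(eff_c + eff_i)/eff_i ≥ 1, fold change = fidelity ratio between enzymes.
Published tables conventionally round efficiencies to two significant
figures before the quotient; the `as_printed` mode reproduces that, and
`none` keeps full precision.  Neither mode is universally closer to
typeset values, which is why both exist.

## FRET

Wavelength grids are supplied in nm and converted to cm internally so the
overlap integral J = ∫E_D(λ)ε_A(λ)λ⁴dλ carries M⁻¹cm³ with the donor
emission area-normalized over the common support (raw-intensity mode
available).  With J in those units, R₀ = 9.78×10³(κ²η⁻⁴f_d J)^{1/6}
yields Ångströms; defaults κ² = 2/3 (dynamic isotropic average),
η = 1.344 (Tris buffer), f_d = 0.7 (IAEDANS).  J ≈ 2.36×10⁻¹⁴ M⁻¹cm³
reproduces the working Förster radius of 37.76 Å for the
IAEDANS–dabcyl pair.  Efficiencies outside [0, 1] (baseline noise) warn
rather than clip, and distance conversion refuses E ∈ {0, 1} where the
law degenerates.

## Kinetic mechanism

Species: E, D, N, E·D, E·D·N (open ternary), E′·D·N (closed), E″·D·N
(post-second-step), E·D₊₁ (product complex), P.  Concentrations are μM
throughout; bimolecular rates μM⁻¹s⁻¹ (DNA binding quoted in nM⁻¹s⁻¹ is
converted, K_d(DNA) 2 nM WT / 5.75 nM variant as the midpoints of the
measured ranges).  dNTP binding is physically an equilibrium constraint
(K₂ = K_d(dNTP)); it is realized as fast association at a diffusion-scale
default of 100 μM⁻¹s⁻¹ with dissociation = K_d × association — a modeling
convention, flagged as such, that leaves observable kinetics insensitive
to the association value provided it is much faster than the
conformational steps.  Product release is one lumped reversible step
(default ~1.3 s⁻¹, the steady-state scale), configurable off.

Measured defaults: fingers closing k₊₃ = 124 s⁻¹ (WT) / 4.73 s⁻¹
(variant), opening k₋₃ = 11.5 / 48.2 s⁻¹, second-step reverse k₋₄ = 4.05
/ 163 s⁻¹, chemistry k₊₅ = k_pol = 12.0 / 3.6 s⁻¹ with k₋₅ = 0.  The
forward second-step rate k₊₄ is reported only as "similar" between
enzymes; the default 40 s⁻¹ is a documented placeholder of that order,
and it is one of the free parameters in fitting anyway.

Integration uses LSODA at rtol 10⁻⁸/atol 10⁻¹² (rates span four orders
of magnitude); enzyme and DNA moiety conservation is asserted to 10⁻⁶
relative after every simulation.  Mixing happens at t = 0 but the first
usable datum sits after the 2 ms instrument dead time, so fitting always
integrates from zero and evaluates at the masked times.  Global fitting
optimizes the free rates in log₁₀ space (positive, badly scaled) with
per-trace amplitudes and baseline profiled out by linear least squares at
every iteration; constrained rates never enter the optimizer.  Parameter
covariance comes from JᵀJ; a condition number above 10¹² marks the free
set unidentifiable.

The trap experiment (pre-formed ternary complex + excess unlabeled trap,
so released dNTP never rebinds) relaxes as a sum of exponentials.  One-,
two- and three-exponential models are fitted and compared by AIC; rates
are reported sorted descending and assigned in reverse-pathway order
(fastest ↔ k₋₄, middle ↔ k₋₃, slowest ↔ dNTP release governed by the
binding equilibrium).  Adjacent rates within a factor 1.5 set an
`ambiguous` flag instead of silently committing to that order.

## CPMG

The fast-exchange profile is evaluated through a numerically safe
tanh(x)/x (series below x = 10⁻⁸), which pins the limits R₂(τ_cp→0) = R₂⁰
and R₂(τ_cp→∞) = R₂⁰ + R_ex exactly.  "Fits preferentially over a flat
line" is operationalized as an F-test on the nested pair (flat = 1
parameter, dispersive = 3) at α = 0.05, with AIC as an alternative mode;
no specific criterion is standard in the field, and the F-test gives a
calibrated false-positive rate under the flat null (verified ≤5% by
simulation).  Flexibility requires both the model preference and
R_ex > 2 s⁻¹.  Fits are per-residue (no shared k_ex), matching how
flexibility counts are reported; Δω is angular (rad/s).  Input grids may
be given as 1/τ_cp directly or as ν_CPMG (Hz) with 1/τ_cp = 2ν_CPMG
(τ_cp = spacing between successive 180° pulses).

## Synthetic data

The generators emulate the statistical structure each analysis assumes,
not the instruments: peak lists are seeded random ILV-like positions
(¹H 0–1.5 ppm, ¹³C 9–27 ppm, residues 1–335) with open→closed
displacements of 0.12–0.45 ppm in the scaled plane, test states
interpolated at closure fraction f, off-pathway peaks rotated exactly 90°
in the scaled plane (so their intended class is analytic), and Gaussian
position noise.  Kinetic curves come from the model equations at the
study conditions (burst 100 nM / 9 s⁻¹ / 1.2 s⁻¹; saturation 12 s⁻¹ /
1.5 μM over the 0.5–1500 μM titration); stopped-flow traces from the
mass-action scheme at 0.25 μM enzyme / 0.1 μM DNA post-mix with a 2 ms
dead-time cut; trap traces as triple exponentials at (163, 48.2, 5) s⁻¹;
CPMG panels of 26 flat + 14 dispersive residues at 0.2 s⁻¹ noise on a
9-point ν_CPMG grid; spectra as Gaussian bands (donor peak 490 nm) or
rectangles with a closed-form overlap.  Identical seeds give
byte-identical outputs; every noise-free output is exactly invertible by
its paired fitting stage (round-trip suite).

What passing these tests does **not** show: real spectra have peak
overlap, assignment errors and field-dependent shifts; real quench data
have gel-quantification noise that is neither Gaussian nor homoscedastic;
real stopped-flow traces carry mixing artifacts beyond a clean dead-time
cut; real dispersion data leave the fast-exchange regime.  The suite
validates the estimators against their own model classes and calibration
against their stated nulls, not robustness to those effects.

## Problem sizes

Default test and acceptance runs use 40-peak lists, 30–40-point progress
curves, 12-concentration saturation series, four stopped-flow
concentrations at 500 points, 25-replicate recovery ensembles and a
1000-replicate null calibration — sizes at which every estimator's
behavior is already asymptotic while the full suite runs in about a
minute.

## Known limitations

* The burst fitter assumes both phases are present; it refuses rather
  than extrapolates when the burst is unresolvable.
* The global fit's amplitude profiling assumes the observable is linear
  in species concentrations (true for FRET quenching at low optical
  density); inner filter effects would need an explicit observable model.
* The trap-step assignment is by rate ordering, not by spectroscopic
  identity; the `ambiguous` flag is the only guard when rates approach
  each other.
* Confidence regions are local (JᵀJ); no profile-likelihood or
  contour search is implemented.
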