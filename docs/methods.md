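# Methods

This note documents the models implemented in `flashsr`, the assumptions
behind them, the defaults and why they were chosen, the numerical
controls, and what the synthetic-data generators do and do not emulate.

## Source model

The source is treated as an ideal isomagnetic bending magnet. Practical-unit
closed forms are used throughout:

- U [keV] = 88.5 · E⁴[GeV] / ρ[m]  (energy radiated per electron per turn)
- P [W] = U [keV] · I [mA]  (the keV·mA product is exactly a watt)
- P/L = P / (2πρ)  (power per metre of bending path)
- E_c [keV] = 2.218 · E³[GeV] / ρ[m]  (critical energy)

The single-electron photon-number spectrum is the universal synchrotron
shape dN/dE = (P_e/E_c²)(9√3/8π) ∫_ξ^∞ K₅⁄₃(x) dx with ξ = E/E_c and
P_e the turn-averaged radiated power of one electron. Its defining
properties — the energy-weighted integral equals P_e, the photon-number
integral equals (15√3/8)·P_e/E_c, and E_c splits the radiated power into
equal halves — are verified by adaptive quadrature in the test suite to
0.5 % relative. The Bessel tail ∫_ξ^∞ K₅⁄₃ is evaluated by adaptive
quadrature with the integrand truncated where it falls below ~1e-30
(x ≈ 70); for ξ < 1 the integrable x^(−5/3) leading behaviour is
integrated analytically and only the regular remainder is quadratured.

Machine defaults (packaged in `data/cepc.yaml`) are the CEPC Higgs-mode
storage-ring values: E = 120 GeV, ρ = 10 700 m, bend angle 2.844 mrad,
242 bunches, revolution frequency 3003 Hz, bunch duration 14.7 ps. The
stored current is not part of the published source figures; the CDR
design value I = 17.4 mA is used as the default and is a plain config
parameter. With it the closed-form photon rate per metre evaluates to
≈ 2.51 × 10¹⁶ m⁻¹s⁻¹, about 6 % above the published 2.363 × 10¹⁶
(which implies I ≈ 16.4 mA); whole-magnet photon rates are therefore
computed from an explicitly supplied per-metre rate when reproducing
published numbers.

The pulse arithmetic is exact bookkeeping: 242 × 3003 = 726 726 pulses/s,
dose per pulse = mean dose rate / pulse rate, instantaneous rate = dose
per pulse / bunch duration. Note that 8.435 Gy per pulse over 14.7 ps is
5.74 × 10¹¹ Gy/s; a commonly quoted figure of 5.74 × 10¹² Gy/s for the
same configuration is a factor of ten larger than this arithmetic and is
not reproduced here.

## Dosimetry conventions

The mean dose rate is Ḋ = e·q_e·N / (V·ρ_m): per-photon energy deposit
e (eV) times the photon rate N over the scoring-voxel mass. The deposit
e is a transport result and is always supplied explicitly; no absolute
dose rate is claimed by this package. (For orientation: the published
6.13 × 10⁶ Gy/s at N = 7.19 × 10¹⁷ /s corresponds to e ≈ 53.2 eV into a
1 mg voxel.)

Depth-dose and profile analysis follows the 85 %-of-d_max convention:
the effective treatment range is the contiguous interval around the
global maximum where dose ≥ 0.85·d_max, with boundaries located by
linear interpolation between samples (deterministic and testable; curve
reading by eye has no stated rule). On multi-modal curves the interval
containing the global maximum is reported and other super-threshold
lobes are listed separately. Boundaries that run off the sampled support
are clamped and flagged. Profile effectiveness is the fraction of
sampled positions inside a window whose dose lies within
[0.85·d_max, d_max].

## Radiolysis kinetics

### Network

The packaged network (`data/water_radiolysis.yaml`) has exactly nine
species: e_aq⁻, O₂, H₂O₂, OH•, H•, H₂, O₂•⁻, R•, ROO•. Primary
radiolytic yields are the standard low-LET photon G-values
(e_aq⁻ 0.28, OH• 0.28, H• 0.062, H₂ 0.047, H₂O₂ 0.073 µmol/J); the
fast aqueous radical reactions carry the recommended pulse-radiolysis
rate constants. Biology enters through pseudo-first-order contractions:
H-abstraction from biomolecules RH (OH• → R• at 4 × 10⁸ s⁻¹, H• → R• at
1 × 10⁸ s⁻¹, the cellular scavenging capacity), superoxide dismutase
(O₂•⁻ → ½H₂O₂ + ½O₂ at 2 × 10⁴ s⁻¹), catalase clearance of peroxide,
and reduction of ROO• by cellular antioxidants (10 s⁻¹). Oxygen starts
at the physioxic 50 µM. The file is the model definition — every number
in it is editable, and the YAML reader/writer round-trips it.

Two deliberate simplifications:

- **No oxygen re-supply.** Diffusive reoxygenation during protracted
  irradiation is a transport process outside the mass-action contract of
  this module. Its omission removes one contributor to dose-rate
  dependence at very low dose rates; the dominant FLASH mechanism
  retained here is radical–radical recombination (R• + R•, ROO• + ROO•)
  competing with pseudo-first-order detoxification.
- **Continuous delivery.** Irradiation is a single continuous block of
  duration D/Ḋ; the bunch structure is ignored. Published kinetic work
  comparing pulsed and continuous delivery puts the difference at the
  few-percent level, below the accuracy of the network itself.

With these defaults the mechanism behaves as follows: the total radical
production per gray is fixed by the G-values, so at conventional dose
rates the instantaneous radical concentrations stay low, bimolecular
self-termination is negligible, and the ROO• exposure integral is set by
the linear detoxification channel — proportional to dose and independent
of dose rate (the plateau). As delivery time shrinks below the ~0.1 s
detoxification timescale, concentrations transiently rise by orders of
magnitude, quadratic recombination dominates, and the exposure per gray
falls to a floor. The transition is sigmoid in log₁₀(dose rate), centred
near a few Gy/s at 10 Gy for these parameters.

### Integration

The ODE system is stiff (rate scales from 10⁻² to 10¹⁰ s⁻¹). It is
integrated with the implicit BDF method with an analytic mass-action
Jacobian, relative tolerance 1e-8 and absolute tolerance 1e-15 mol/L.
(LSODA was tried first and suffered repeated Newton convergence failures
on the long conventional-dose-rate legs.) Beam-on and beam-off legs are
integrated separately so the production discontinuity at t = D/Ḋ never
sits inside a solver step. The exposure integral ∫[ROO•]dt is carried as
an auxiliary quadrature state, so it inherits solver accuracy instead of
output-grid trapezoid error; linear toy networks reproduce closed-form
AUCs to better than 1e-4 relative. Output concentrations more negative
than −max(10³·atol, 1e-12) mol/L raise a diagnostic error; in practice
excursions stay below 1e-15.

The followup window defaults to 100 s, long enough for ROO• (lifetime
≤ 0.1 s under the default detoxification constant) to decay to a
negligible rate; the AUC is insensitive to extending it. The exposure
window includes the followup — damage accrues as long as the radical
persists, and for protracted delivery the "during irradiation" and
"total" integrals coincide anyway.

### Surface and surrogate

N(D, Ḋ) is tabulated on a dose × log-spaced dose-rate grid (defaults:
4 doses 5–30 Gy × 11 rates 10⁻²–10⁷ Gy/s; one stiff integration per
point) and each dose row is normalized by its value at the lowest grid
dose rate, so N = 1 on the conventional anchor column and N ∈ (0, 1].
The tabulated surface is compressed into

    N(D, Ḋ) = 1 − a(D) / (1 + exp(−(log₁₀ Ḋ − b(D)) / w))

by bounded least squares (polynomials in D of degree 3 by default, a
shared width w ∈ [0.02, 5] decades, row-wise asymptote/midpoint initial
guesses). This functional form is a reconstruction: it is the simplest
shape consistent with a sigmoid dose-rate dependence between a plateau
at 1 and a floor 1 − a(D), with polynomial dose dependence of amplitude
and midpoint. Surfaces generated from the form itself are refit to
machine precision; the canonical network's surface fits with a maximum
absolute residual of ~0.02 (asserted < 0.05 in the tests).

A structural consequence of per-dose-row normalization: at conventional
dose rates N ≈ 1 for *every* dose, so the composed NTCP cannot
distinguish doses there, and along an iso-NTCP contour the tolerated
dose varies with dose rate only through a(D) and b(D). On the canonical
network a(D) increases with dose (stronger relative self-quenching at
higher radical load), which makes the tolerated dose at a fixed NTCP
level non-increasing across the FLASH transition and undefined (flagged
NaN) outside it. An un-normalized exposure model would instead show
tolerated dose growing with dose rate; users wanting that behaviour
should work with the raw AUC matrix, which the surface object retains.

## NTCP model

NTCP(N) = expit(γ(N − m)), evaluated through `scipy.special.expit` /
`log_expit` so that γ ≈ 1320 never overflows. The packaged default
(γ = 1320, m = 0.2002) is the literature estimate obtained from thirteen
groups of animal toxicity data; it ships as data, not as something this
package re-derives.

Fitting maximizes the binomial log likelihood of grouped outcomes
through the composed model (a least-squares mode against observed
fractions is provided for digitized dose-response inputs). The optimizer
is a vectorized scan over a (log₁₀γ, m) grid followed by a Nelder–Mead
polish that is accepted only if it genuinely improves the objective.
The grid tie-break matters: with a steepness of order 10³ the logistic
transition spans ΔN ≈ 4/γ ≈ 0.003, narrower than the spacing of any
realistic thirteen-group design, so observed groups are all-or-nothing
and the likelihood is *exactly flat* (to machine precision) over a
region of parameter space — m anywhere in the separation gap, γ
anywhere above a design-dependent floor. The fitter reports the flattest
defensible point estimate: the smallest steepness on the plateau and the
objective-minimizing midpoint (≈ the gap midpoint). Consequently:

- m is recovered to within the separation gap of the design (about
  ±0.09 for the default thirteen-group layout), not better — no
  data-driven estimator can do better;
- γ is a lower bound, not an estimate; its bootstrap distribution
  collapses onto the plateau onset;
- in the identifiable regime (shallow sigmoids, well-populated groups
  with intermediate response fractions) the same fitter recovers both
  parameters accurately, as the test suite demonstrates.

The confidence region is a seeded parametric bootstrap (default 1000
replicates): responders are redrawn from the fitted model and refitted;
95 % percentile intervals are reported together with the seed.

Tolerated-dose curves solve NTCP(D, Ḋ) = level for D by bracketed
Brent root finding (xtol 1e-8; the residual in NTCP is well below 1e-6);
dose rates where the level is unreachable inside the dose bounds yield
flagged NaN entries rather than extrapolation.

## Synthetic data

The generators stand in for every external input so the chain runs
offline:

- **Toxicity designs** mirror the scale of the published fit: 13 groups
  at 10 Gy, dose rates log-spaced 10⁻²–10⁷ Gy/s, 50 subjects per group,
  binomial outcomes drawn from the composed model at the true
  parameters. Group placement is deterministic; the seed controls only
  the binomial draws. The default reference surrogate is a fixed
  constant-in-dose snapshot of the canonical network's fitted surface
  shape at 10 Gy (a = 0.94, b = 0.45 decades, w = 0.59 decades).
- **Toy networks** (production–decay, linear chain, oxygen capture)
  carry their closed-form solutions as metadata and are the exactness
  oracles for the integrator.
- **Depth-dose fixtures** (triangle, flat, buildup–exponential) are
  analytic shapes for the curve utilities, optionally with seeded noise.

What passing tests on synthetic data do **not** show: that the shipped
rate constants reproduce any particular animal experiment; that binomial
outcome noise is the right error model for digitized literature points;
or that real toxicity data would constrain γ (see above — with a steep
sigmoid it cannot). They do show that the chain is internally
consistent, deterministic under a seed, and correct wherever a closed
form exists.

## Known limitations

- The radiolysis rate constants for the biology-facing channels are
  order-of-magnitude cellular values, not measurements; the network file
  is meant to be edited.
- No radiation transport: per-photon energy deposits, beamline spectra
  and absolute dose rates at the phantom are inputs.
- No oxygen diffusion, no track-structure micro-dosimetry, no immune or
  DNA-repair component, no tumour-control modelling.
- γ is structurally unidentifiable from separated grouped data; treat
  fitted steepness values as plateau onsets and rely on the reported
  bootstrap intervals.
- The surrogate is fitted over doses 5–30 Gy and dose rates 10⁻²–10⁷
  Gy/s; evaluations outside the fitted support are extrapolations of the
  polynomials a(D), b(D).
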