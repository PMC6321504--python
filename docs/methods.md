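# Methods

## Geometry and the forward model

The laboratory frame follows the standard fiber-photometry convention: OZ is
the muscle-fiber axis, OY the propagation direction of both the exciting and
the collected light, and the two polarizer settings select OZ ("parallel")
or OX ("transverse") for excitation and emission independently, giving the
quadruple (‖I‖, ‖I⊥, ⊥I⊥, ⊥I‖) ≡ (I_pp, I_pt, I_tt, I_tp).  Each component
is a photoselection average ⟨(a·ê_exc)²(e·ê_em)²⟩ over the orientation
distribution of absorption (a) and emission (e) transition dipoles.

**Ordered population.**  Probes decorate the actin helix, so their dipoles
sit on cones about the local filament axis with half-angles Φ_A (absorption)
and Φ_E (emission).  The azimuths of the two dipoles on their cones are
averaged uniformly and *independently* — the ensemble of probes is spread
along the helical repeat, and the intensity of the ensemble is the sum over
spiral positions.  With that averaging, the mean squared projection of a
cone dipole onto a lab axis has the closed form

    f_Φ(c²) = cos²Φ·c² + sin²Φ·(1 − c²)/2,   c = w·ê,

where w is the filament axis, and every intensity factorizes into
⟨f_A(·) f_E(·)⟩ over the filament-wobble distribution.  This construction is
what makes the classical magic-angle statement exact: for collinear dipoles
on a rigid cone (γ = 0, θ½ = 0) both polarization ratios vanish together at
Φ = arccos(1/√3) = 54.7356°.  A fully correlated (rigid-pair) ordered model
was evaluated and rejected: it moves the P_‖ = P_⊥ crossing to ≈ 52°,
contradicting the magic-angle behavior this class of measurements is
interpreted with.  The inter-dipole angle γ still matters through the
Φ_A–Φ_E tie (below) and through the disordered branch.

**Filament wobble.**  The filament axis deviates from the fiber axis by a
polar angle θ_f with uniform azimuth.  θ½ is defined as the *maximal*
deviation; the default density is uniform in the polar angle on [0, θ½]
(the simplest distribution honoring that definition).  A uniform-over-
solid-angle alternative is available as a configuration switch
(`Quadrature(wobble="solid_angle")`).

**Disordered population.**  A fraction N of probes is static and
isotropically oriented, modelled as a rigid dipole pair at fixed angle γ
with the textbook closed forms: parallel-polarizer components
∝ (1 + 2cos²γ)/15, crossed components ∝ (2 − cos²γ)/15, i.e. fundamental
anisotropy r₀ = (3cos²γ − 1)/5.  The mixture is component-wise,
(1 − N)·ordered + N·isotropic, with no per-population renormalization (both
populations share absorption cross-section and quantum yield); the model is
defined up to one common positive scale and all comparisons are made on
sum-normalized quadruples.

**Sign convention for N.**  The reported quantity N is the *disordered*
fraction throughout (rising N = probes detaching from the ordered lattice,
as when myosin heads release F-actin under MgATP).

**Dipole tie.**  The inverse problem would be under-determined with both
cone angles free, so Φ_A is tied to the fitted Φ_E through the dye's fixed
inter-dipole angle: Φ_A = Φ_E − γ (or Φ_E + γ when Φ_E < γ), i.e. coplanar
dipoles.  Built-in γ values: 20° (1,5-IAEDANS on S1 Cys707), 14°
(FITC-phalloidin on actin), 17° (5-IAF on Tpm Cys190).  The general
azimuthal offset δ solving cos γ = cosΦ_A cosΦ_E + sinΦ_A sinΦ_E cos δ is
exposed as a geometry helper.

**Quadrature.**  The filament azimuth is integrated on a uniform periodic
grid (64 points; the integrand is a degree-4 trigonometric polynomial, so
any grid ≥ 5 points is already exact) and the wobble polar angle by 32-node
Gauss–Legendre; the dipole azimuths are analytic.  An optional convergence
check re-evaluates at doubled resolution and raises if agreement is worse
than 10⁻⁶ relative.  A seeded Monte-Carlo sampler of the same distribution
serves as the independent oracle in the test suite (agreement within 3
standard errors of the MC mean, ≲10⁻³ relative).

## Inverse fitting

Per fiber, (Φ_E, N, θ½) minimize the SSR between sum-normalized observed and
model quadruples, with bounds Φ_E ∈ [0°, 90°], N ∈ [0, 1], θ½ ∈ [0°, 60°].
The SSR is evaluated on a deterministic 45-point start grid
(Φ_E ∈ {15…75}, N ∈ {0.1, 0.5, 0.9}, θ½ ∈ {5, 25, 45}); the 8 best starts
are polished by bounded least squares (ftol 10⁻¹⁴) and the global best is
returned — fits are therefore reproducible bit-for-bit on identical input.
A fit is flagged `degenerate` when two polished minima within SSR 10⁻⁶
differ by > 2° in Φ_E or > 0.05 in N, and `disordered_only` when N ≈ 1 (the
ordered-population parameters are then meaningless).  Noise-free round
trips over the feasible domain recover Φ_E and N to machine precision
(asserted at 0.1° / 0.005 with SSR ≤ 10⁻¹⁰).

Ensembles report the mean ± SEM of each parameter over fibers (SEM is
undefined and flagged for a single fiber); failed fibers are excluded and
counted.

## Stiffness and its identifiability limit

The semiflexible-filament relation for a filament of length L fixed at one
end, sin²θ = 0.87·(kT/ε)·L, converts the wobble angle to a bending
stiffness.  Defaults L = 1 μm and T = 293.15 K (room temperature) are
configuration values; with these, reported stiffnesses of a few
10⁻²⁶ N·m² imply wobble angles of ~9–17°.  The two conversions are exact
mutual inverses on their shared domain; ε values implying sin²θ > 1 are
rejected ("filament too soft"), and sin²θ = 1 is flagged as the 90°
boundary.

θ in this relation is taken to be θ½ itself (the maximal deviation as drawn
in the geometry), not an RMS angle.

**Identifiability.**  The sensitivity of the normalized quadruple to θ½ at
small wobble (~9°, cone angles near 55°) is ≈ 5×10⁻⁴ per degree — the
weakest direction of the fit by two orders of magnitude (SVD of the forward
Jacobian).  Under 2% per-component intensity noise, single-fiber θ̂ is
therefore undetermined to roughly ±7°, and per-fiber ε = 0.87kTL/sin²θ̂, a
reciprocal of a small noisy quantity, has no finite moments (it diverges as
θ̂ → 0).  Consequences for the implementation:

* ensemble stiffness is reported as 0.87kTL / mean(sin²θ̂), never as a mean
  of per-fiber ε;
* the significance of a mutant-vs-WT stiffness change is tested on the
  per-fiber sin²θ̂ values (∝ 1/ε) and the sign flipped;
* stiffness contrasts of less than about an order of magnitude should not
  be expected to reach significance from 8–10 fibers at 2% noise when the
  underlying wobble is below ~15°.  Cone angles and disordered fractions do
  not share this limit (their sensitivities are 40–700× larger) and carry
  the classification in practice.

## Actin-frame correction

The tropomyosin probe reports its angle in the laboratory frame, but actin
monomers themselves rotate between conditions; tropomyosin angles are
therefore re-expressed relative to the rotating F-actin helix:

    corrected Φ_E = Φ_E(Tpm) − (Φ_E(actin) − Φ_E(actin, reference)).

The reference is the S1-free, low-Ca²⁺ (blocked-state) actin condition by
default and is configurable.  The correction is invariant under adding a
common constant to both actin angles; results outside [0°, 90°] are clamped
with a warning.

## ATPase analysis

Raw activities are corrected by subtracting the S1-alone baseline and
normalized to the shared post-subtraction maximum (idempotent; replicates
share one maximum).  The Hill equation in pCa,
a = floor + amplitude/(1 + 10^(n_H(pCa − pCa50))), is fitted by bounded
least squares (pCa50 ∈ [4, 8], n_H ∈ (0, 6], floor ∈ [−0.2, 0.5],
amplitude ∈ (0, 1.5]) from a pCa50 start grid {5, 6, 6.5, 7, 7.5};
replicates enter one joint SSR rather than being averaged first (preserves
the error structure; negligible difference for balanced designs).  Standard
errors come from the Jacobian at the optimum; fits at a bound are flagged,
flat curves rejected.  Only pCa50 is interpreted downstream; n_H is fitted
but the simulation default n_H = 1.5 reflects typical thin-filament
cooperativity.

## Mutant-vs-WT comparison and classification

Per shared condition (probe target × Ca × nucleotide × S1), mutant and WT
fiber ensembles are compared per parameter with a two-sample two-sided
Student's t-test (equal variances — the field's historical default; Welch
is a configuration switch).  p < α (default 0.05) yields an up/down call by
the sign of the mean difference, else norm; two degenerate zero-variance
samples compare exactly.

The 15-feature signature maps calls to physiology: a *decrease* in Φ_E(Tpm)
means a shift toward the inner actin domain (feature up); Φ_E(actin)
follows switched-on monomer counts directly; strong binding of myosin heads
requires *concordant* decreases of both Φ_E(S1) and N(S1) — discordant
evidence yields a missing feature and a logged conflict.  Calcium
sensitivity is up/down when |ΔpCa50| > 0.1 with non-overlapping standard
errors.  The reference matrix stores one row per characterized mutation
(with stiffness, reported once per mutation, filling both the high- and
low-Ca stiffness features) plus sparse per-myopathy consensus rows encoding
the discriminating strong-binding patterns (CFTD: up/up; Cap: down at high
Ca, up at low Ca with ATP; NM: down/down; DA: up at high Ca with normal
TN-shift features).  Classification is nearest-neighbor normalized Hamming
distance over mutually non-missing features; equal distances prefer the
reference with more compared features, and a second myopathy group within
one feature of the best sets a tie flag.  The trinary encoding cannot
express magnitude distinctions (e.g. NM's "more pronounced" strong-binding
decrease vs Cap), which is a known limitation.

## Synthetic data

The generator emulates the full study design: per condition, n_fibers
(default 10) quadruples from the forward model of a true orientation state,
each component multiplied by unit-mean lognormal noise with CV 2% (chosen so
simulated ensemble SEMs resemble typical reported error bars); per variant,
a triplicate ATPase table on the pCa 8 → 4 ladder (step 0.25) with additive
Gaussian noise (σ = 0.03) and a constant baseline column.  Everything is
deterministic under (scenario, seed).

Wild-type truths anchor every published worked value of the γ-tropomyosin
system (tropomyosin corrected angles 56.7/58.6° without S1 and 54.2/54.7°
in rigor, 54.8° under ATP; tropomyosin stiffness 13.9×10⁻²⁶ N·m² falling
to 7.5×10⁻²⁶ under ATP; actin angles 48.4 → 47.5° with stiffness
4.2 → 5.5×10⁻²⁶; myosin-head angles 44.7 → 51.2° with disordered fractions
0.393/0.432 → 0.576; pCa50 6.84/6.92/7.33/6.69 for E173A/R90P/E150A/A155T
vs 6.5 for WT).  Unpublished entries were fixed once at field-realistic
values: disordered fractions 0.20 (Tpm probe) and 0.25 (actin probe),
S1-probe wobble 25°, low-Ca angles within 1.5° of their high-Ca partners
preserving every published difference.  Mutant scenarios apply the trinary
reference row of the packaged signature matrix to the WT table with fixed
magnitudes — 2.0° on cone-angle features, 0.08 on disordered fractions,
×/÷1.7 on stiffness — documented as illustrative sign structure, not
measured effect sizes.

**What passing tests do and do not show.**  The generator draws from the
same forward model the fitter inverts, with independent per-component
noise; recovery tests therefore validate the inverse machinery and the
statistical pipeline, not the adequacy of the helix-plus-isotropic model
for real fibers.  Real data add systematic effects outside the model —
instrument depolarization, photobleaching, fiber-to-fiber γ variation,
parameter scatter between fibers (the generator puts all variance in
measurement noise) — and those are deliberately not emulated.

## Numerical conventions

Angles are degrees at every interface (radians internally); stiffness is
printed in 10⁻²⁶ N·m²; intensities are arbitrary common units, compared
sum-normalized.  Optimizer tolerances: ftol/gtol 10⁻¹⁴, xtol 10⁻¹²,
≤ 400 function evaluations per start.  The problem sizes exercised by the
test and acceptance suites — 8–10 fibers per condition, 12 conditions per
variant, 100-state round-trip sweeps, 10⁶-draw Monte-Carlo oracles, 100–200
seeded Hill fits — are the package's standard verification design.
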