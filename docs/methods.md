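# Methods

## Probe liquids and the acid–base model

The three-liquid scheme decomposes a surface tension into a
Lifshitz–van der Waals (dispersive) component and Lewis acid/base
parameters, γ = γ^LW + 2√(γ⁺γ⁻). The default probe set is the van Oss
reference set at room temperature, in mJ m⁻² (≡ mN m⁻¹):

| liquid        | γ_total | γ^LW | γ⁺   | γ⁻   |
|---------------|---------|------|------|------|
| water         | 72.8    | 21.8 | 25.5 | 25.5 |
| formamide     | 58.0    | 39.0 | 2.28 | 39.6 |
| diiodomethane | 50.8    | 50.8 | 0    | 0    |

Published characterization tables rarely print the liquid constants they
used; this set was validated by forward/inverse consistency against the
reference tables the regression suite carries (the glass and
polycarbonate rows reproduce to within the rounding of the printed
angles). Some methodology sources circulate slightly different formamide
parameters; the set above is the one validated here, and any liquid can
be overridden through the `liquids:` section of a YAML run config. The
registry enforces γ_total = γ^LW + 2√(γ⁺γ⁻) to 0.1 mJ m⁻² and is
immutable at run time. Temperature dependence is out of scope; angles
are degrees at every API surface.

## Inverting the Young–Dupré equations

The apolar (diiodomethane) equation gives γ_s^LW = γ_D(1 + cos θ_D)²/4 in
closed form; the water and formamide equations then form a 2×2 linear
system in a = √γ_s⁺, b = √γ_s⁻. A singular system (polar liquids with
proportional acid/base character) raises a solver error naming the rows.

**Negative-root convention.** For strongly monopolar surfaces (most
commercial polymers) the linear solve returns a < 0. The solver carries
the magnitudes into γ⁺ = a², γ⁻ = b², γ_AB = 2|a||b| and every ΔG_coh
cross term, and records the signs in `root_sign_flags`. This is the
convention that reproduces published total energies for such materials
(e.g. polycarbonate at 57.1 mJ m⁻²); clipping the root to zero would
not. Flagged surfaces are warned about at characterization time so the
convention is auditable.

Mean angles per surface are computed before inversion (matching how
replicate measurements are reported, as mean ± SD of n = 3); replicate
noise propagates only through the synthetic-recovery tests.

**Forward map and spreading.** The forward evaluation (components →
angles) is the test oracle for the inversion. A component set whose work
of adhesion against some liquid exceeds 2γ_L spreads that liquid
completely; the forward map returns θ = 0 in that case rather than
failing, since superwetting is physical — but it loses information, so
round-trip identity tests restrict themselves to strictly non-wetting
component sets. cos θ < −1 cannot occur for non-negative components and
is guarded only defensively.

**Tolerances.** Published tables print angles rounded to 1°. Propagating
±0.5° through the inversion moves ΔG_coh by up to ~2 mJ m⁻² for
high-angle surfaces, so exact ±0.5 mJ m⁻² reproduction from printed
angles is only attainable for some rows. The regression suite therefore
asserts ±0.5 for the rows where the arithmetic supports it and, for
every row, that the printed value lies inside the interval attained over
the 3³ grid of ±0.5° angle perturbations (with 0.06 slack for the
printed values' own rounding). One printed τ₀ cell is internally
inconsistent with its own printed water angle and is excluded.

## Wettability metrics and classification

τ₀ = γ_w cos θ_w. Vogler's criterion is applied strictly: τ₀ > 30 mJ m⁻²
is hydrophilic, the boundary value hydrophobic. The threshold is a
config parameter.

γ_c is the Zisman extrapolation: OLS of cos θ against γ_L over all three
liquids, solved for cos θ = 1. The three probe liquids are deliberately
not chosen for Zisman work (they differ in polarity, not just tension),
so the fit can be poor — the r² diagnostic is reported and fits with
r² < 0.9 are warned about rather than silently dropping liquids. Plain
Zisman regression on published mean angles does **not** reproduce the
γ_c values printed alongside them (glass computes to ≈ 90 mJ m⁻² against
a printed 56.7; the source's calculation method is not recoverable from
its text), so γ_c is validated only by properties: exact recovery of
synthetic angle sets generated from a true Zisman line, and the
degenerate zero-slope error path. The Baier minimal-fouling band is not
numerically fixed in the source literature either; the default closed
interval [20, 30] mN m⁻¹ follows the Baier-curve literature and is
configurable.

## Surface zeta potential

Near-wall tracer readings (125–625 µm) are fitted by OLS against
displacement; ζ_s = −intercept + ζ_m with ζ_m the far-field (1000 µm)
tracer value, which is excluded from the regression (electro-osmosis
dominates near the wall, electrophoresis far from it). The model is
linear by design — matching how the measurement is extrapolated in
practice — not an electrokinetic decay model, and no Smoluchowski/Henry
conversion is attempted (the instrument's mobility-to-zeta step is
upstream). Signs are kept as reported. No published raw profiles exist
to regress against, so validation is by construction: exact recovery of
noise-free lines (residuals < 1e-9 mV), agreement with the closed-form
normal equations, and Monte-Carlo mean recovery of a configured wall
potential to 0.5 mV over 200 noisy profiles (1 mV instrument noise —
the SE of that mean is ~0.07 mV, so the bound is comfortable but not
trivial).

## Orbital shear rate

γ_ω = r_eff·√(ρ(2πf)³/μ). The lumped effective length r_eff = 0.0275 m
is the unique value consistent with the documented operating map
(50/100/150 rpm → 329/932/1712 s⁻¹ with water, ρ = 1000 kg m⁻³,
μ = 10⁻³ kg m⁻¹ s⁻¹); whether it represents orbital radius, dish radius
or a combined coefficient cannot be determined, so it is exposed as a
config parameter with this provenance. The f^{3/2} and √(ρ/μ) scalings
are asserted algebraically.

## Adhesion normalization and grouping

Relative adhesion is 100·(m/A)/(m_ctl/A_ctl); the control is identified
by configuration (borosilicate glass in the reference protocol, with a
BSA adsorption capacity of 3.0 µg cm⁻² on 18.75 cm² coupons). One-way
ANOVA is computed from direct sums of squares (the MSE and error df are
needed for the LSD anyway) and cross-checked in tests against
`scipy.stats.f_oneway`. Fisher's LSD at level α uses
t_{1−α/2,df_e}·√(2·MSE/n), with the harmonic mean of group sizes for
unbalanced designs (the reference design is balanced at n = 3, so this
only affects generality). Letters come from the insert-and-absorb
compact-letter-display algorithm: treatments share a letter iff their
mean difference is below the LSD; overlapping letter sets are legal,
contradictions are not, and input order makes the output deterministic.
Zero within-group variance makes F degenerate; letters then fall back to
exact-tie comparison and the result is flagged. Two-way
material×roughness interaction modelling is out of scope.

## Synthetic data

Generators are pure functions of (config, seed) via
`numpy.random.default_rng`.

* **Contact angles:** true angles from the forward Young–Dupré map of a
  material's components, plus Gaussian noise on the *angles* (matching
  how replicate SDs are reported), truncated to [0, 180). Defaults:
  n = 3 replicates, SD = 2° (reported replicate SDs run 1–5°).
* **Truth library:** six reference materials. Because the magnitude
  convention can assign monopolar polymers a γ⁺ whose forward map would
  superwet formamide, the shipped truths are the closest *physical*
  component sets (bounded least squares, a, b ≥ 0) to the published mean
  angles; their forward angles stay within a few degrees of the
  published ones, and the glass entry is the exact hand solve
  (40.6, 0.511, 50.9).
* **Zeta:** linear near-wall profiles at the standard stations
  {125, 250, 375, 500, 625} µm plus the 1000 µm far-field point,
  Gaussian noise (default 1 mV), default intercepts −60 mV (negatively
  charged walls).
* **Adhesion:** Gaussian replicate masses with a fixed CV (default
  0.03) per material×Ra×EPS-type on 18.75 cm² coupons, control pinned at
  3.0 µg cm⁻².

What the generators do *not* emulate: angle hysteresis and drop-volume
effects, roughness-dependent (Wenzel/Cassie) angle shifts, non-linear
zeta decay, ionic-strength effects, or adsorption kinetics. Passing
recovery tests therefore demonstrates the *estimators* are correct under
the assumed noise model, not that real measurements satisfy that model.

## Problem sizes

Round-trip and oracle tests use 1000 and ~50 random component sets;
Monte-Carlo recoveries use 200 (zeta) and 500 (angles, adhesion power)
seeds; ANOVA agreement uses 100 random balanced designs. The full suite
runs in a few seconds on one CPU.

## Known limitations

* γ_c from the three standard acid–base probe liquids is a diagnostic,
  not a faithful Zisman measurement; treat it (and the Baier label built
  on it) with the r² in view.
* The magnitude convention for negative roots is an empirical
  reconciliation with published tables, not a thermodynamic derivation;
  monopolar results should be read as effective parameters.
* The shear-rate formula is a lumped engineering estimate for
  non-breaking waves in an orbiting dish, not CFD.
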