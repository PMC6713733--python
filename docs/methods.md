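# Methods

## Model

The microtubule outer surface is an `h × p` lattice of binding sites
(αβ-tubulin dimers, 8 nm), with `p = 13` protofilaments and a seam
between the first and last protofilament.  A Tau molecule binds
reversibly in one of two modes: longitudinally along a protofilament
("p", covering `1 + σ_p` consecutive dimers of one column) or laterally
along the helix ("h", covering `1 + σ_h` dimers across adjacent
protofilaments).  Binding is saturable and exclusive — no partial,
overlapping or stacked binding — the protofilament axis has open ends,
and lateral molecules may not cross the seam.  Bound Taus do not
interact otherwise (no cooperativity).

At equilibrium the coverages `ρ_p, ρ_h` (bound Tau per site) satisfy

    ρ_i / (x − ρ_p − ρ_h) = k_eq,i · Φ_i(ρ_p, ρ_h),   i = p, h,

where `x` is the Tau:tubulin-dimer ratio, `k_eq,i = N[MT]/K_d,i`, and
`Φ_i` is the probability that one more Tau in mode i fits on the
partially covered lattice.  Treating each lattice line as a homogeneous
one-dimensional gas of the projected particles gives the closed form

    Φ_p = A^(1+σ_p) / (1 − σ_p ρ_p)^σ_p,
    A   = 1 − (1+σ_p) ρ_p − (1+σ_h) ρ_h,

and symmetrically for Φ_h; `Φ = 1` on the empty lattice and `Φ = 0` on
the saturation line `A = 0`.  For point particles (σ = 0) the convention
`(1 − σρ)^σ ≡ 1` applies, so `Φ = A`.

This closure is derived from a geometric gap model: along the
protofilament direction the projected particle density is
`ρ_∥ = ρ_p + (1+σ_h)ρ_h` and the gaps between consecutive particles are
geometric, `f(g) = (1−u)u^g` with `u_∥ = A/(1 − σ_p ρ_p)`.  Summing the
`g − σ` insertion positions of a size-`1+σ` particle over that gap law
reproduces the closed form exactly (asserted to 1e−12 in the tests); the
finite-line variant `Φ = (ρ + 1/ℓ) Σ (g−σ) f(g)` with maximum gap `A·ℓ`
is also exposed and converges to the closed form as `ℓ → ∞`.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `σ_p, σ_h` | extra sites covered per mode | 1 | stoichiometry ν = 1/2, the consensus literature value |
| `k_eq_p, k_eq_h` | dimensionless equilibrium constants | 1 | axonal estimates span 0.1 ≤ k_eff ≤ 10³ |
| `x` | Tau:tubulin-dimer ratio | 1 | axonal range 0.1–10 |
| `h × p` | lattice size | 615 × 13 | a 4.9 µm, 13-protofilament microtubule |
| `site_length_nm` | dimer length | 8 nm | unit conversion only |

Values of `x` or `k_eff = k_eq_p + k_eq_h` outside the axonal ranges
produce warnings, never errors: the mathematics is valid beyond them.
Setting one `k_eq` to 0 encodes the single-mode limit; the inactive
coverage is pinned to exactly 0 rather than special-cased elsewhere.

## Equilibrium solver

The single-mode equation is solved by bracketed Brent iteration on
`[0, min(x, 1/(1+σ))]`, where the residual provably changes sign.

The two-mode system is reduced to one dimension: for every trial `ρ_h`
the p-mode equation has a unique root `ρ_p*(ρ_h)` (its two sides are
monotone in opposite directions), found by Brent; the remaining scalar
equation in `ρ_h` is scanned on a 400-point grid for sign changes and
each root is polished by a damped Newton iteration (analytic Jacobian,
backtracking line search restricted to the open physical triangle,
residual tolerance 1e−10).  Near saturation the availability `A` is
computed by cancellation and caps the attainable residual around 1e−12;
the polish accepts convergence at the 1e−10 tolerance there.

The root scan exists because the coupled system is **not always
unique**: for unequal binding sizes the two modes compete through their
different footprints and the system can be genuinely multistable.  For
example σ_p = 2, σ_h = 3, k_eq,p = 3.25, k_eq,h = 9.75 has three
equilibria at x = 6.9 that collapse through a fold near x ≈ 6.94 (the
Jacobian determinant vanishes there, which is why plain continuation in
x cannot pass it).  When several equilibria coexist the solver returns
the one dynamically selected from the empty lattice, obtained by
integrating the relaxation equations `dρ_i/dt = −F_i` from the origin
(LSODA, rtol 1e−10) and matching the attractor to the nearest root —
the equilibrium an adsorption experiment starting from bare microtubules
would reach.  For equal binding sizes no multistability has been
observed and the scan finds a single root.

The dilute closed form (the quadratic root of the single-mode isotherm
linearized in the gap structure) is provided separately and agrees with
the full solver to <1 % for ρ ≲ 0.05.

## Phase portraits

The trajectory of `(ρ_p, ρ_h)` under varying `x` at fixed
`κ = k_eq,p/k_eq,h` satisfies a single algebraic relation obtained as
the ratio of the two isotherms.  It is traced by pseudo-arclength
continuation from the origin: the residual is kept in polynomial form
(multiplying through by a power of `A` when σ_p < σ_h) so it stays
defined on the boundary, the tangent is the rotated numerical gradient,
and each predictor step is corrected by Newton along the gradient to
|residual| < 1e−13.  Arc-length continuation is required because for
σ_p ≠ σ_h the curve is bi-valued in ρ_p (it turns back toward the
corner of the higher-stoichiometry mode).  The endpoint on the
saturation line is computed separately: a 1-D Brent solve for equal
sizes, the exact corner `(0, 1/(1+σ_h))` or `(1/(1+σ_p), 0)` otherwise.
Degenerate κ (0 or ∞) returns the corresponding axis segment.  For equal
sizes the κ and 1/κ portraits are exact mirror images, which the tests
assert through the residual of the swapped points.

## Spacing statistics

Along direction k the nearest-neighbor center-to-center distance r (in
site units) is distributed as

    P_k(r) = Σ_ij z_k,i z_k,j (1 − u_k) u_k^(r − r_k,ij),

a mixture over the four ordered mode pairs, each shifted to its
close-packing distance `r_k,ij` (diagonal: `1+σ` for the extended mode,
1 for the projected one; off-diagonal: `1 + σ_k/2`, half-integer for odd
σ).  The weights `z_k,i` are the directional coverage fractions: an
h-mode Tau crosses `1+σ_h` protofilament lines and is counted that many
times along ∥, and vice versa.  The center convention — a p-mode Tau
anchored at i has center `i + σ_p/2` on its column; an h-mode Tau
occupies a single site per column — reproduces those packing distances
exactly and matches the simulation census.  Distributions live on an
r grid with step 0.5 truncated at a retained-mass tolerance of 1e−13
(so truncated first moments match the closed-form means to ~1e−8); the
mean is `u/(1−u)` plus the z-weighted mean close packing, which reduces
to `1/ρ` (single p) and `1/((1+σ_h)ρ)` (single h) and to
`1/(1 − σ_p ρ_p,s)` at saturation.  Only the long-lattice limit is
exposed; finite-line corrections are O(1/h) and invisible at
microtubule length along ∥ (but see Accuracy below for the 13-site ⊥
lines).

## Monte Carlo simulation

The simulator is a Gillespie (kinetic Monte Carlo) chain implementing
exactly the binding rules above on the full lattice.  Only rate ratios
matter at equilibrium, so off-rates are fixed to 1 — time is measured in
mean bound lifetimes — and the per-anchor attach propensity in mode i is
`k_eq,i · c_free`, with `c_free = n_free/N` for the default canonical
ensemble (a closed reservoir of `round(x·N)` Tau, honoring x as a
closed-system ratio) or `c_free = x` for the optional grand-canonical
variant.  Detailed balance then gives the stationary measure
`π(C) ∝ k_p^{n_p} k_h^{n_h} M!/((M−n)! N^n)` (canonical), whose
mean-field limit is the equilibrium system above.  The chain was
validated against exhaustive enumeration of that measure on a 4 × 3
lattice (agreement within one standard error).

Implementation notes:

* Admissible anchors per mode are maintained incrementally in dense
  index lists, so a uniformly random anchor is drawn in O(1) even near
  saturation where the admissible set is a vanishing fraction of the
  lattice.
* Configurations are sampled on a **uniform grid of simulated time**
  (default spacing 1 lifetime after a 50-lifetime burn-in), never per
  event: the embedded jump chain weights states by their total exit
  rate and is a biased sample of the continuous-time stationary law
  (on a 2-site toy system the event-sampled coverage is 0.25 against
  the exact 1/3).
* Coverage standard errors use batch means (20 batches), absorbing the
  residual autocorrelation between samples; a Geweke-style drift check
  on the burn-in trace is reported as a warning when the start and end
  of the trace disagree.
* The nearest-neighbor census records distances in half-site bins up to
  30 sites along every protofilament column and helix row, using the
  same center convention as the theory; boundary molecules enter pairs
  without correction, a documented O(r/h) edge effect in far-tail bins.
  Empirical spacing pmfs are normalized over the recorded window, so
  theory must be renormalized over the same window before comparison
  (`SpacingDistribution.pmf_on_grid(..., renormalize=True)`).

Default problem sizes — 615 × 13 sites with 10³–10⁴ sampled
configurations in the validation tests — resolve coverages to a few
10⁻⁴ and histogram bins to ~10⁻⁴–10⁻³ while keeping the whole suite at
desk scale.

## Accuracy of the mean-field theory (what the tests show)

The Monte Carlo chain samples the exact lattice model; the closed-form
theory is a mean-field description.  Their agreement is therefore
layered, and the test suite asserts each layer at its own fidelity:

* **Single p mode, ∥ direction** — the 1-D large-ligand gas on 615-site
  lines is exact in the thermodynamic limit: simulated coverages and
  spacing histograms agree with theory within 3 standard errors across
  the physiological (x, k_eq) grid.
* **Anything involving the h mode** — helix lines are only 13 sites
  long (seam, no wrap), so infinite-lattice theory carries O(1/13)
  corrections; e.g. at x = 10, k_eq,h = 3 the simulated coverage is
  0.442 against the theoretical 0.454.
* **Two coupled modes** — the closure treats each line as an
  independent 1-D gas and ignores inter-line correlations, adding
  systematic per-bin offsets of 0.5–5 % (largest at high coverage, e.g.
  the mixed-pair peak at r = 1.5 for κ = 2, x = 10: simulated 0.328 vs
  theoretical 0.345).

These offsets are systematic, not statistical — no sample size removes
them.  The strict 3-standard-error comparison is asserted verbatim in
`tests/test_acceptance.py` (where the non-exact configurations fail by
design, documenting the closure error), while the regular suite checks
MC against theory at the documented model fidelity (3 SE plus
5·10⁻³ + 8 % of the bin mass) over randomized parameter sets.

## Synthetic data

All inputs are generated internally: the simulator *is* the data
generator, emulating equilibrium decoration of an ideal stabilized
13-protofilament microtubule.  It does not emulate microtubule
curvature, GTP/GDP lattice heterogeneity, Tau–Tau cooperativity,
conformational detail, or dynamic (growing/shrinking) lattices; passing
tests therefore validate the adsorption statistics, not those effects.

## Known limitations

* Time courses are not modeled quantitatively — the kinetic scheme is a
  means of sampling equilibrium, with rates fixed by their ratios.
* The multistability tie-break (relaxation from the empty lattice) is a
  modeling choice; systems prepared differently may sit on another
  stable branch near a fold.
* The 400-point root scan could in principle miss a pair of roots closer
  than its grid spacing; no such case has been observed.
* Snapshot export is plain TSV; no raster image output.
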