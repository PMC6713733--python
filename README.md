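# taudecor

Equilibrium theory and kinetic Monte Carlo simulation of **Tau-protein
decoration of stabilized microtubules**.

Tau is a microtubule-associated protein that binds the outer microtubule
surface and regulates axonal transport and microtubule stability.
Structural evidence supports two binding geometries: a **longitudinal
("p") mode** running along a single protofilament and a **lateral ("h")
mode** spanning adjacent protofilaments along the helix.  `taudecor`
models the microtubule surface as an `h × p` lattice of 8 nm tubulin
dimers (13 protofilaments with a seam) on which Tau adsorbs reversibly in
either mode under strict exclusion, and computes the two observables that
characterize the resulting *decoration*: the surface coverage and the
nearest-neighbor spacing statistics of bound Tau.

The package is for biophysicists analyzing Tau–microtubule binding data
(co-sedimentation isotherms, spacing histograms from EM) and for modelers
who need a validated reference implementation of multivalent-ligand
lattice adsorption with two competing binding footprints.

## Model

A Tau bound in mode *i* covers `1 + σᵢ` consecutive sites (stoichiometry
`νᵢ = 1/(1+σᵢ)`).  With `x = [Tau]/(N[MT])` the Tau:tubulin-dimer ratio
and `k_eq,i = N[MT]/K_d,i` the dimensionless equilibrium constants, the
mean-field equilibrium coverages `ρ_p, ρ_h` (bound Tau per site) solve

```
ρᵢ / (x − ρ_p − ρ_h) = k_eq,i Φᵢ(ρ_p, ρ_h),        i = p, h
Φ_p = A^(1+σ_p) / (1 − σ_p ρ_p)^σ_p,   A = 1 − (1+σ_p)ρ_p − (1+σ_h)ρ_h
```

(and symmetrically for Φ_h) — the two-dimensional analogue of the
McGhee–von Hippel large-ligand insertion factor.  From the solution the
package derives:

* **phase portraits** `ρ_h(ρ_p)` organized by `κ = k_eq,p/k_eq,h`,
  traced to the saturation line `A = 0`;
* **nearest-neighbor distance distributions** `P_k(r)` along the
  protofilament (∥) and helix (⊥) directions — mixtures of geometric
  laws shifted to the close-packing distances, including the
  half-integer `1 + σ/2` offset of mixed p–h pairs — and their means
  `⟨r_k⟩`;
* the **order parameter** `S = (1+σ_p)ρ_p − (1+σ_h)ρ_h` (+1 all
  longitudinal, −1 all lateral);
* a **kinetic Monte Carlo (Gillespie) simulation** of the same binding
  rules on the full 615 × 13 lattice, used to validate the mean-field
  results and quantify where they deviate (see `docs/methods.md`).

## Worked example

Coverages at a physiological low (`x = 0.15`) and high (`x = 10`) Tau
ratio, with both modes active and `κ = 2`:

```sh
$ taudecor equilibrate --x 0.15 --x 10 --keq-p 2 --keq-h 1
x,k_eq_p,k_eq_h,sigma_p,sigma_h,rho_p,rho_h,rho,S
0.15,2.0,1.0,1,1,0.06781508799126945,0.03267580943846157,0.10049089742973102,0.07027855710561576
10.0,2.0,1.0,1,1,0.3218773386376357,0.12468168010952928,0.44655901874716497,0.3943913170562128
```

At `x = 0.15` about 10 % of the lattice sites carry a Tau (ρ ≈ 0.10) and
the decoration is nearly isotropic (S ≈ 0.07); at `x = 10` the lattice is
close to saturation (ρ ≈ 0.45 of the 0.5 maximum for σ = 1) and biased
toward longitudinal Tau (S ≈ 0.39) because the p mode binds twice as
strongly.  The spacing distribution at the same high-coverage point:

```sh
$ taudecor spacing --x 10 --keq-p 0.44 --keq-h 0.22 --direction parallel
r_sites,r_nm,P_total,P_pp,P_ph,P_hp,P_hh
1.0,8.0,0.14064273692247478,0.0,0.0,0.0,0.6982773141798558
1.5,12.0,0.3454764669176648,0.0,0.6982773141798558,0.6982773141798558,0.0
2.0,16.0,0.2545932146650613,0.6982773141798558,0.0,0.0,0.21068610668162274
...
```

The dominant spacing is `r = 1.5` sites (12 nm): the close packing of a
mixed longitudinal–lateral pair, a direct signature of two coexisting
binding modes that no single-mode model produces.

A Monte Carlo run with theory comparison columns:

```sh
taudecor simulate --x 10 --keq-p 0.44 --keq-h 0.22 --seed 1 \
    --n-samples 2000 --compare --out results/
```

writes `summary.json` (coverages with standard errors and provenance),
`spacing_parallel.csv` / `spacing_perp.csv` (measured vs theoretical
histograms) and `snapshot.tsv` (a lossless occupancy table of the final
configuration).

Library use mirrors the CLI:

```python
from taudecor import ModelParams, solve_equilibrium, spacing_distribution

params = ModelParams(sigma_p=1, sigma_h=1, k_eq_p=0.44, k_eq_h=0.22, x=10)
cov = solve_equilibrium(params)          # rho_p, rho_h, S, availability
dist = spacing_distribution(cov, params, "parallel")
print(cov.rho, dist.mean() * params.site_length_nm, "nm")
```

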