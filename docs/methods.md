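# Methods

## Model

A fluid membrane patch is described by Helfrich curvature elasticity with
mean bending rigidity κ, no spontaneous curvature (symmetric bilayer) and
a uniform Gaussian modulus κ̄ that, at fixed topology, contributes only a
constant and is excluded from all minimizations. On the patch sits a
single lipid-segregated domain Ω of fixed area A (the membrane outside Ω
is treated as an energy-free flat reservoir), carrying an ESCRT-rich ring
Γ ⊆ Ω. Four terms compete:

* bending, (κ/2)∮(c₁+c₂)²dA — cost of curving the bud;
* Gaussian coupling, ΔκG ∫_Γ c₁c₂ dA — ESCRTs either bind preferentially
  to saddle-shaped membrane or locally shift the Gaussian modulus; both
  readings give the same linear coupling with contrast ΔκG > 0 favoring
  the negative-Gaussian-curvature bud neck;
* line tension, σ × length of ∂Ω — drives budding by shortening the
  domain boundary;
* binding, −w × Area(Γ) — favors large ESCRT coverage.

Axisymmetric shapes are parametrized by the tangent angle ψ(s) along the
arc length s ∈ [0, s₁], with dr/ds = cos ψ, dz/ds = sin ψ and principal
curvatures c₁ = ψ′, c₂ = sin ψ / r. The Gaussian-coupling integrand
c₁c₂ r = ψ′ sin ψ is a total derivative, so the ring term collapses to
2πΔκG(cos ψ(s_a) − cos ψ(s_b)). The ring's outer boundary coincides with
the domain rim (where ψ = 0 by the smooth-matching condition): a ring
that reaches the rim therefore spans the neck, and only the inner
boundary angle carries information. This convention is used consistently
in the analytic cap model and in the numerics; it is also what an
unconstrained minimization chooses, since extending the ring to the rim
simultaneously maximizes binding and the saddle-coupling gain.

Nondimensionalization: lengths in units of a = √(A/π) (the flat-disc
radius of Ω), energies in units of κ. Three control parameters remain:
p_σ = σa/κ, p_w = wA/κ, p_g = ΔκG/κ.

## Spherical-cap model

The bud is approximated by a spherical cap with budding coordinate
x = (1 − cos α)/2 ∈ [0, 1] and ESCRT area fraction φ ∈ [0, 1]. Two
arrangements are distinguished: the whole domain forms the cap with Γ a
ring reaching the rim (Case I), or only the ESCRT-free patch buds while Γ
remains a flat annulus around the neck (Case II). In κ units

```
E_I  = 8πx − 4π p_g x(1−φ) + 2π p_σ √(1−x)        − p_w φ
E_II = 8πx − 4π p_g x      + 2π p_σ √(1−x(1−φ))   − p_w φ
```

(derivations in the `budkit.cap` docstring; the two cases coincide on the
φ = 0 edge and at x = 0). The determinant of the 2×2 Hessian of either
case is negative everywhere inside the unit square — analytically
−(4πp_g)² for Case I and strictly negative for p_σ > 0 for Case II — so
minima lie at corners: flat (0,1), coated bud (1,1), coatless bud with
neck-localized ESCRTs (1,0), and the zero-radius "mini-bud" (1,1) on the
Case-II surface. Degenerate parameter sets (p_g = 0 for Case I, p_σ = 0
for Case II) have singular Hessians and are excluded from that claim.

Consequences, all verified by the test suite:

* coexistence lines p_σ = 4 (flat/coated), p_w = 4π p_g
  (coated/coatless), 2π p_σ − p_w = 8π − 4π p_g (flat/coatless);
* spinodal p_σ = 8: along the φ = 1 buckling path the energy is
  8πx + 2π p_σ(√(1−x) − 1) + const, whose initial slope changes sign
  there, so budding becomes barrier-free;
* critical domain radii R_coex = 4κ/σ and R_spin = 8κ/σ (ratio exactly
  2), and the bud radius R* = R_spin/2 = 4κ/σ — set by material
  parameters only;
* the three-stage route (flat → coated bud → ESCRTs drain to the neck,
  all downhill) requires wA/4π < ΔκG < 2κ; above 2κ the flat state is
  unstable and ESCRT-free mini-buds form first, squeezed larger by line
  tension provided the domain radius stays below σ/w — on that route the
  ESCRTs never coat the bud.

Barriers are measured along the unit-square edge path
(0,1) → (1,1) → (1,0), on the Case-I surface inside the coupling window
and on Case II above it, as max(E along path) − E(start). Interior
saddles, when present, lie above the corner minima; `global_minimum`
verifies this with a dense two-surface grid scan on every call.

## Numerical minimization

ψ(s) is expanded in a sine series Σ aₙ sin(nπs/s₁) (default N = 30
modes; the diagram-level drivers use N = 12), which enforces ψ(0) =
ψ(s₁) = 0. Because ψ depends on s only through s/s₁, the domain-area
constraint A = 2π∫r ds fixes s₁ in closed form (area ∝ s₁²), and every
energy term evaluates on the unit interval: bending is scale invariant,
line and binding terms carry explicit powers of s₁. The ring boundaries
are held as fractions (t_a, t_b) of s₁ so area rescaling never moves
them off the contour.

Minimization is simulated annealing (Metropolis walk over the N
amplitudes and two ring fractions, geometric cooling from T = 20κ with
factor 0.93, move widths adapted toward ≈40% acceptance, inadmissible
shapes — negative radius or amplitude beyond the smoothness cap
|aₙ| ≤ 4π/n — rejected at any temperature), followed by a deterministic
refinement: bounded L-BFGS-B descent from the annealed state, from
structured ring placements (full coverage; a window around the neck), and
from canonical flat/pre-formed-bud shapes. Each parameter point is run
from ≥ 2 independent initial configurations (flat disc; pre-formed bud;
then random) and flagged converged only if the restart minima agree
within 0.5κ. Identical seeds give bit-identical results.

Quadrature: the annealing evaluator uses composite trapezoid on a
uniform grid (the cumulative integral for r(u) is then a cumulative sum;
one evaluation costs tens of microseconds), with 193 nodes in the
diagram drivers. Reported final energies are recomputed through the
geometry/energy modules: composite Simpson on 1025 nodes, exact area
re-enforcement, and cubic-spline interpolation for partial-range areas.
Closed-form fixtures (flat disc, caps, sphere-with-catenoid-neck) sample
r and the curvatures analytically, so pointwise identities (c₁+c₂ = 0 on
a catenoid) hold to machine precision; piecewise contours place panel
boundaries at the junctions to keep Simpson's order. The pole 0/0 in
c₂ = sin ψ/r is closed by its limit c₂ → c₁.

## Classification and diagnostics

Minimum-energy configurations are grouped as flat (bending < 0.4κ),
ESCRT-coated bud (area fraction φ = A_Γ/A_Ω > 0.8) or coatless bud
(otherwise); the thresholds were calibrated once against the analytic
cap-model labels on a reference grid and are arguments everywhere. The
boundary tangent-angle diagnostic cos ψ is taken at the ring's inner
boundary (the outer one sits at the rim where ψ ≡ 0); it moves from +1
(coated: ring starts at the pole) to ≈ −1 (coatless: ring starts past
the dome) abruptly at the coated/coatless transition, together with the
area fraction, while the minimum energy itself is continuous. The neck
diagnostic is the rms mean curvature over the ring: zero for an exact
catenoid, 1/ρ for a spherical ring.

## Resolution limits of the shape ansatz

The truncated Fourier ansatz cannot close the bud neck completely: the
minimum energy in the budded phases sits above the corresponding cap
corner by a variational offset that decays only like ~1/√N (≈ 4.3κ at
N = 30, ≈ 2.6κ at N = 64 for p_σ = 8). Morphology labels, area
fractions, tangent-angle diagnostics, phase boundaries and pathway logic
are insensitive to this offset and reproduce the cap model; absolute
minimum energies in the budded phases are upper bounds. The same slow
convergence leaves truncation curvature in the neck's termination region,
so the rms mean curvature over the full ring of an annealed bud stays of
order the dome curvature even though the ring passes through genuinely
minimal-surface (c₁+c₂ ≈ 0) material; the exact-catenoid score is
meaningful for constructed shapes and as a relative diagnostic.

## Synthetic data and scope

There are no external data: all test inputs are closed-form reference
shapes (flat disc, spherical caps, sphere-with-catenoid-neck) generated
at run time, plus seeded random profiles and random parameter draws. The
fixtures exercise exactly the geometry the model assumes — axisymmetric,
single bud, sharp domain boundaries, Γ a single ring. Passing tests
therefore validate the elastic model and its implementation, not effects
deliberately outside it: membrane tension and volume constraints,
thermal shape fluctuations, finite bilayer thickness (relevant for the
mini-bud route), ESCRT-III scission, demixing thermodynamics beyond a
phenomenological line tension, or non-axisymmetric shapes. Temperature
or composition dependence of σ is not modeled.

## Default parameters

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| bending rigidity | κ | 10 | kT | between early-endosome (~4 kT) and liquid-ordered GUV values |
| Gaussian contrast | ΔκG | 10 (= κ) | kT | mid-window: wA/4π < ΔκG < 2κ |
| line tension | σ | 1–2 | kT/nm scale | GUV domain-boundary measurements span this range after rescaling |
| binding strength | w | ~0.005 | kT/nm² | keeps wA below the 4πΔκG window bound at R ≈ 50 nm domains |
| domain area | A | πa² | nm² | a is the experimentally relevant domain radius |

The default morphology diagram fixes p_g = 1 (ΔκG = κ), which places
the three-region topology (flat at small p_σ; coated at large p_σ, large
p_w; coatless at large p_σ, small p_w) comfortably inside the sampled
window p_σ ∈ [1.5, 10.5], p_w ∈ [3, 27].
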