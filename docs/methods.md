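# Methods

`osteogrow` simulates how bone grows into the pores of a swelling
co-polymeric bone anchor, and what that ingrowth does to the anchor's
stiffness and fixation strength.  This note documents the models, the
numerical choices, and — importantly — what the desk-scale 2D reduction can
and cannot reproduce.

## Physical picture

A porous MMA/AA (85/15) co-polymer anchor is press-fit into a drilled bone
tunnel.  In situ it absorbs interstitial fluid and swells; because the
surrounding bone confines it, swelling builds a compressive radial stress at
the bone–anchor interface (expansion-fit fixation) and hoop tension in the
bone.  That radial stress is also a mechanical stimulus: it loads the pore
space, and bone remodels into the pores, starting at the interface and
advancing inward through interconnected pores.  Filled pores stiffen the
anchor and bond it to the bone, so push-out strength rises.

## Geometry: emulated salt-leached porosity

Porosity is created in manufacture by leaching randomly mixed NaCl crystals.
The generator emulates this with overlapping disks (spheres in 3D) whose
diameters are uniform in a band (defaults 300/450/600 ± 100 µm), placed
uniformly inside the anchor cross-section until a target void fraction
(default 60%) is reached, with a ±2% acceptance window.  Overlap is allowed
and unresolved: pore interconnectivity is *emergent*, exactly as in the real
process, and void components with no adjacency path to the interface ("pore
islands") are detected and reported, never repaired.  A candidate pore that
would overshoot the porosity window is redrawn; placement is fully
deterministic for a given seed.

The default domain is a quarter cross-section (two symmetry planes) of a
4 mm-radius anchor with a 2 mm out-of-plane slice thickness and a 1 mm bone
layer (thickness our choice; it only needs to be a few pore diameters to act
as the confining ring).  Meshing is a structured "pixel FEM": a square grid
of right triangles, each labelled ANCHOR / VOID / BONE by centroid
membership, with a 0.05 mm default seed.  The element adjacency structure
(the osteoconnectivity matrix) stores edge-sharing neighbours; it is built
once per mesh and drives both island detection and the ingrowth gate.

What this does not emulate: controlled-interconnectivity architectures
(TPMS lattices), body-fitted smooth pore walls, and — critically — the
three-dimensionality of real pores.  In plane strain every pore is an
infinite axial channel; see *Limitations*.

## Hygro-elastic swelling

Moisture uptake enters as an isotropic eigenstrain
ε_hs = β_h (α_m − α_m,ref), with β_h = 0.9920 m³/kg and
α_m = 0.08672 kg/m³ for the 85/15 co-polymer (ε_hs = 0.08603).  No
diffusion equation is solved: the equilibrium moisture content is imposed
uniformly in the anchor material, and the time dependence of pressure
build-up is represented downstream by a load ramp.  Elasticity is
small-strain, linear, plane strain, with the out-of-plane eigenstrain
component retained, so a fully confined element carries the hydrostatic
stress −E ε_hs/(1 − 2ν) = −74.5 MPa — the analytic anchor for the solver's
eigenstrain path.  The wet modulus (433 MPa, ν = 0.25) is used for the
swollen anchor, 1940.48 MPa / 0.34 for bone, and a 0.05 MPa / 0.3 dummy
material for unfilled voids.

The area-weighted average radial stress over the interface,
σ̄_rr = ∫σ_rr dA / A, is the single scalar handed to the ingrowth stage.
Face samples average the two adjacent element stresses and project onto the
radial direction; the rasterised staircase overestimates the true arc
length by ~4/π, so force-type quantities are rescaled to the smooth arc
area (π/2)·R·t.

## Remodeling with an osteoconnectivity gate

Each element is a basic multicellular unit with apparent density ρ
(g/cm³).  The stimulus is strain energy density per unit density,
S = U/ρ (J/g), and density evolves by the lazy-zone law

    dρ/dt = B (S − (1+δ)k)   if S > (1+δ)k
          = 0                 if (1−δ)k < S < (1+δ)k
          = B (S − (1−δ)k)   if S < (1−δ)k

with B = 1 (g/cm³)²/(MPa·t.u.), k = 0.004 J/g, δ = 10%, integrated by
forward Euler with Δt = 0.01 and clamped to 0.01–1.7 g/cm³.  Units are
chosen (mm–MPa–g/cm³) so U in J/cm³ is numerically MPa and S lands directly
in J/g.

Unlike site-independent remodeling, densification is *gated*: in iteration
1 only void elements on the interface (open pore throats) are eligible;
afterwards a void element becomes permanently eligible once any neighbour's
density exceeds α × that neighbour's initial density.  α = 1 is the relaxed
gate (any growth unlocks the neighbourhood), α = 1.25/1.5 moderate/strict.
Growth therefore propagates as a front, at most one adjacency layer per
iteration, never nucleates in pore islands, and never retreats (eligibility
is permanent; eligible elements keep updating until bounds or homeostasis).
The loop stops when no element changes by more than 2% in an iteration, or
at the iteration cap.

Numerical choices:

* **Density-step limiter.**  A dummy element under direct load can have
  S ~ 10³–10⁵ J/g, and a raw Euler step would teleport it to the density
  bound — a truncation artefact of explicit integration on a stiff system,
  not remodeling.  Steps are therefore limited to 0.1 g/cm³ per iteration
  (~6% of the density range); configurable, `None` disables.
* **Load ramp.**  The interface pressure is applied with an exponential
  saturation ramp p_i = p(1 − e^{−i/τ}), τ = 10 iterations, standing in for
  the gradual build-up of swelling pressure over implantation time
  (sorption kinetics); configurable.
* **Load placement.**  The pressure acts on anchor-owned interface faces
  (the polymer–bone contact); an open pore mouth transmits nothing until
  bone occupies it.  The pore space is loaded through the deformation of
  the surrounding skeleton.
* **E(ρ) law.**  The modulus of remodeling elements follows a power law
  through the two printed calibration points, (0.01 g/cm³, 0.05 MPa) and
  (0.8 g/cm³, 1940.48 MPa), giving exponent γ ≈ 2.41 — inside the classical
  density-squared-to-cubed range for trabecular bone.  Configurable.
* **Stimulus strain.**  U uses the mechanical strain (total minus
  eigenstrain), so a stress-free swollen state carries no stimulus.
* **Filled volume ratio.**  Defined as the void-volume fraction occupied by
  grown elements (any strict density increase).  A density threshold
  variant (e.g. ≥0.4 g/cm³) is available; the default was chosen because
  the reference results' printed fill ratios track their grown-element
  counts, not a half-bone-density cut.

## Mechanical characterization

**Axial stiffness** is the apparent modulus of the cross-section under a
prescribed uniform axial strain with free in-plane relaxation (generalized
plane strain).  A homogeneous prism returns exactly E; a porous section
returns roughly the solid area fraction times E, and post-ingrowth
densities raise it monotonically (guaranteed, since elementwise stiffness
only increases).

**Push-out** is displacement-controlled axial extraction at constant
(held) swelling pressure.  The anchor translates axially as a rigid body;
the interface resists through

* Coulomb friction on anchor–bone contact faces: elastic stick of
  stiffness G/h per unit area, capped at μ·p·A_contact (μ = 0.4).  The peak
  pre-ingrowth force is exactly the Coulomb capacity, linear in μ and p.
* post-ingrowth, elastic–plastic shear springs on grown pore-throat faces:
  Johnson–Cook hardening σ_y = A + B ε^n (A = 0.05 GPa, B = 0.1 GPa,
  n = 0.08), von Mises shear conversion, strength scaled by
  min(1, (ρ/0.8)²) for immature bone, and erosion (face deletion) at 3%
  equivalent plastic strain — bone's ultimate strain scale; 0.3 would let
  the hardening term grow far past any reported bone strength.  Eroded
  faces carry nothing, so after complete bond failure the reaction decays
  to the friction floor.

This interface model satisfies the invariants one would demand of the full
FEM (exact Coulomb proportionality, post > pre, monotone erosion, energy
dissipation ordering) at a fraction of the cost, but it mobilises all bond
faces simultaneously, making its post-ingrowth peak an upper bound — see
below.

## Reference study and problem sizes

`osteogrow.studies.reference_study` (also behind `scripts/acceptance.py`)
runs, per master seed: five small-pore (300 µm) realisations — swelling,
relaxed-gate ingrowth to iteration 40, strict-gate to 25, stiffness and
push-out pre/post — and five medium-pore (450 µm) realisations to iteration
40.  Meshes are ~15,700 elements (≈6,000 void); the full study is ~1,300
sparse solves and runs in about a minute on one CPU.  The 22 MPa interface
pressure reported for the reference 3D swelling simulations is the default
handoff load; the package's own 2D swelling value can be substituted
(`load_pressure: null`).

## Limitations (what passing tests do and do not show)

The plane-strain reduction changes two things qualitatively, both verified
rather than hidden:

1. **Percolation.**  At 60% porosity, 2D through-channel pores nearly
   disconnect the solid: the porous cross-section retains only ~2–4% of the
   solid section's swelling pressure (solid: ≈26 MPa, matching a two-ring
   Lamé estimate; porous: ≈0.6–1 MPa).  A 3D porous anchor keeps far more
   of its stiffness at equal porosity.
2. **Stimulus scale.**  With the reference 22 MPa load on the compliant
   2D section, void-element stimulus saturates (S ≫ k) almost everywhere
   behind the front.  The ingrowth front is then purely gate-limited: the
   relaxed front advances ~0.7 element layers per iteration (void-network
   tortuosity under edge-sharing adjacency), the strict gate slows it only
   marginally, and grown elements climb toward the density ceiling, which
   inflates the post-ingrowth stiffness gain and bond strength.  In a 3D
   structure at matched load/stiffness ratio, void strains sit near the
   lazy-zone boundary, which is where gate strictness and gradual density
   tracks differentiate.

Quantities that are contact- or geometry-dominated (pre-ingrowth push-out,
added mass, porosity statistics, all property invariants) transfer well to
the 2D model; quantities that depend on the 3D stimulus distribution
(strict-gate slowdown, stiffness recovery percentage, post-ingrowth
push-out peak) should be read as qualitative in 2D.  The rigid-translation
push-out bond model is an upper bound on the post-ingrowth peak, since a
compliant 3D structure fails its bond line progressively.

All defaults live in `RunConfig` and serialise to YAML; a config file plus
one integer seed reproduces every number in this note's pipeline
bit-for-bit on a given platform.
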