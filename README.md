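# osteogrow

Adaptive finite-element prediction of bone ingrowth into porous **swelling
bone anchors** — and of what that ingrowth does to their stiffness and
fixation strength.

Swelling co-polymeric anchors (hydrophobic/hydrophilic MMA/AA networks)
fixate by an *expansion-fit* mechanism: they absorb interstitial fluid,
swell against the bone tunnel, and hold by radial pressure and friction
rather than thread shear.  The same radial stress is a mechanical stimulus.
`osteogrow` couples three stages to study this:

1. **Hygro-elastic swelling.**  Moisture uptake is an isotropic eigenstrain
   ε_hs = β_h(α_m − α_ref); solving the constrained elasticity problem for
   the anchor in its bone layer yields the average radial interface stress
   σ̄_rr = ∫σ_rr dA / A — the load on everything downstream.
2. **Osteoconnectivity-gated remodeling.**  Each element carries an
   apparent density ρ driven by the strain-energy stimulus S = U/ρ through
   the lazy-zone law dρ/dt = B(S − (1 ± δ)k), forward-Euler integrated and
   clamped to [0.01, 1.7] g/cm³.  An element adjacency matrix *gates*
   densification: only pore elements next to the bone interface may grow
   first, and an element unlocks its neighbours only after its density
   exceeds α × its initial value.  Bone therefore forms **sequentially**
   from the interface inward (α = 1 relaxed … 1.5 strict controls the
   rate), and isolated "pore islands" never grow.
3. **Mechanics.**  Apparent axial stiffness pre/post ingrowth (generalized
   plane strain), and displacement-controlled push-out with Coulomb
   friction (μ = 0.4) plus Johnson–Cook plasticity (σ_y = A + Bεⁿ) and
   erosion of the newly formed interface bone.

Synthetic geometry is first-class: quarter-slice anchors with salt-leached
porosity emulated by overlapping random pores (300/450/600 ± 100 µm bands,
~60% porosity), rasterised to a structured triangle mesh with full
adjacency, boundary-set and pore-island analysis.  Intended users:
computational biomechanics researchers studying implant osteointegration
and porous implant design.

## Worked example

Grow bone into a small-pore (300 µm) anchor for 25 iterations under the
22 MPa swelling interface pressure, relaxed gate:

```bash
$ osteogrow ingrow --pore-mean 300 --seed 7 --load 22 --alpha 1.0 --iterations 25
{
  "load_MPa": 22.0,
  "alpha": 1.0,
  "iterations_run": 25,
  "converged_at": null,
  "depth_mm": 0.8322370318752976,
  "filled_volume_ratio": 0.2980221253771372,
  "added_mass_g": 0.0025300985922585917,
  "grown_count": 1778
}
```

Reading the numbers: after 25 iterations the ingrowth front has advanced
0.83 mm radially inward from the interface; 1,778 of the ~6,000 pore
elements have densified (30% of the void volume), adding 2.5 mg of bone to
the 2 mm quarter slice.  Homeostasis (`converged_at`) has not been reached —
the front is still moving.  The same pipeline is scriptable from Python:

```python
from osteogrow import (PoreSpec, generate_porous_domain, mesh_domain,
                       extract_anchor_submesh, RemodelingParams, run_ingrowth)

dom  = generate_porous_domain(PoreSpec(300, 100, 0.60, rng_seed=7))
mesh = mesh_domain(dom, element_size=0.05)
sub  = extract_anchor_submesh(mesh)
hist = run_ingrowth(sub, load_pressure=22.0,
                    params=RemodelingParams(alpha_gate=1.0, max_iterations=25))
print(hist.depth_mm[-1], hist.grown_count[-1])
```

Other subcommands: `osteogrow generate` (geometry + pore statistics + VTK),
`swell` (σ̄_rr from constrained swelling), `compress` (pre/post stiffness),
`pushout` (peak fixation force), `campaign` (all pore bands × seeds, CSV/JSON
report), `write-config` (YAML defaults).  Exit codes: 0 success, 2 config
error, 3 numerical failure.

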