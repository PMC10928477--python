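# Methods

`spinesim` simulates the early structural enlargement of a dendritic spine
after long-term potentiation (sLTP) as a moving-boundary problem: lattice
reaction–transport equations for the actin machinery, coupled to a
triangulated membrane that moves under bending and polymerization forces.
This note documents the model, the discretizations, the parameter choices,
and what the synthetic data and scaled-down runs can and cannot show.

## Model

**State.** Three scalar fields on a fixed cubic lattice (spacing Δx):
`B`, the number density of actin-filament barbed ends (#/μm³), and the
concentrations `A` (Arp2/3) and `C` (cofilin) in μM; plus a closed triangle
mesh Γ for the spine membrane with per-vertex positions **s** (μm), anchored
by a fixed set of dendrite-base vertices in the plane z = 0.

**Membrane coupling.** Every lattice point carries the signed distance
d_s(r, Γ) to the membrane (negative inside), the outward unit direction
d = ∇d_s, a soft repulsive potential

    ψ(r, Γ) = α tanh(β d_s)/2,

and the confining force density f_u = −∇ψ = −(αβ/2) sech²(β d_s) d.
As α, β → ∞ the membrane becomes a hard reflecting wall; at the calibrated
α = 3·10⁴ pN, β = 40 the wall is soft with width 1/β = 25 nm.

**Barbed ends.**

    ∂B/∂t = −∇·(ν d B) + η ∇·(f_u B) − k_β B
            + Ψ₀ (f_nuc + f_sev + I_β + I_S,β)

with polymerization speed ν along d, effective filament mobility η coupling
the confining force to transport, basal efflux k_β, Arp2/3 side-branching
nucleation f_nuc = k_nuc A Ψ₁ B, cooperative cofilin severing
f_sev = k_sev Cⁿ/(k_n + Cⁿ) Ψ₁ B, and influx terms (below). Ψ₀ converts μM
to #/μm³ and Ψ₁ the reverse.

**Arp2/3 and cofilin** advect toward the membrane by bulk flow at speed
ξ ν_mp along d (ν_mp is the tracked protrusion velocity, ξ < 1 a crowding
restriction), degrade at k_A, k_C, are consumed by nucleation/severing, and
share the influx geometry.

**Force balance.** With inertia negligible, F_actin + F_mem + F_drag = 0 and
F_drag = −ω dΓ/dt gives the overdamped update dΓ/dt = (F_mem + F_actin)/ω.
F_mem is the negative gradient of the Helfrich bending energy
E_mem = κ/2 ∫ H² dA with zero spontaneous curvature; F_actin is the negative
gradient of the overlap energy E_B = ∫_Ω ψ B dr, which converts barbed ends
near the membrane into outward push.

## Discretizations

**Bending.** Cotangent Laplace–Beltrami with barycentric dual areas:
E_mem = κ/2 Σ_v |K_v|²/A_v, where K_v is the integrated mean-curvature
vector (the gradient of total area). The curvature convention is
H = c₁ + c₂, so a sphere of any radius has E_mem = 8πκ (verified within
0.5% on a subdivided icosphere). The bending force is the *exact* analytic
gradient of this discrete energy, derived by reverse-mode differentiation
through cotangents and dual areas; a central-finite-difference oracle
agrees to ~10⁻⁷ relative. Exactness matters: it makes the membrane update a
true gradient flow (energy descent is monotone under backtracking) and
keeps the force test falsifiable.

**Actin force.** E_B is discretized as Σ_{r interior} ψ(d_s(r)) B(r) Δx³.
Because d(point, mesh) is a min over elements, Danskin's theorem gives
∂d_s/∂s_i = −b_i d for the vertices of the closest element (b_i the
barycentric weight of the closest point). Each interior lattice point
therefore distributes an outward force B Δx³ (αβ/2) sech²(β d_s) d over the
closest face's vertices by barycentric weight. This is again the exact
gradient of the discretized energy (finite-difference oracle ≤ 10⁻³).

**Distance queries.** Closest-element queries are exact: a KD-tree over
face centroids only *prunes* candidates using the nearest-vertex distance
(or a warm start from the previous closest face) as an upper bound, and the
per-triangle closest-point arithmetic is identical to an exhaustive scan —
results are bitwise equal to brute force, ties resolving to the lowest face
index. Inside/outside uses angle-weighted pseudo-normals of the closest
feature, which are sign-exact for watertight meshes even when the closest
feature is an edge or vertex.

**Transport stencils.** First-order upwind for the advective derivatives
(polymerization of B, bulk flow of A and C), central differences for ∇·d,
∇·f_u and f_u·∇B, one-sided at the lattice boundary. Negative undershoot
from upwinding is clipped to zero after each step and the clipped mass is
logged (it stays many orders of magnitude below the influx). Time stepping
per global Δt uses adaptive RK45 sub-stepping (relative tolerance 10⁻⁶ by
default); a pure-decay configuration matches e^(−kt) to 10⁻⁶ over 60 s at
tightened tolerance. The severing rate clamps C at zero before the
fractional Hill power so adaptive sub-steps that probe slightly negative
concentrations remain finite.

**Remeshing.** Incremental isotropic remeshing (split > 4/3·Δs, collapse
< 4/5·Δs with link-condition and normal-flip guards, valence-driven edge
flips, tangential relaxation with projection onto the pre-remesh surface).
Fixed vertices are never moved or removed; splitting a fixed–fixed base
edge creates a new fixed vertex in the dendrite plane. Volume drift per
remesh is guarded (< 1% near the target resolution; a deliberate
coarsening pass inherently trades inscribed volume on curved regions and
uses a 5% guard at construction time). Repeated remeshing of an
already-isotropic mesh drifts ~0.2% per call as vertices re-seat on the
piecewise-linear reference.

**Initial shape.** A surface of revolution: cylinder (radius r_n) from the
dendrite plane to its tangential junction with the head sphere at
z_j = z_c − √(R² − r_n²), then the sphere, closed by a base disc whose
vertices are the fixed dendrite set. With the default head (R = 0.25 μm at
z_c = 0.85) and neck (r_n = 0.1 μm, nominal length 0.6 μm) the junction
sits at z_j ≈ 0.62 μm; extending the cylinder to the junction avoids the
degenerate point-tangency that a hard 0.6-μm cutoff would create. The
shape is then bending-relaxed (actin force off) to a stable configuration
before the lattice is initialized.

## Influx geometry, stimulus, boundaries

Basal influx is distributed uniformly over all interior lattice points of
the spine head (z ≥ 0.6 μm); each point receives rate/n_basal, so the
*total* protein delivery is independent of the lattice resolution. Species
start at the reaction-only fixed point of that system (total barbed ends
Ψ₀ I_β/k_β ≈ 10 857, Arp2/3 I_A/k_A ≈ 19.6 μM, cofilin I_C/k_C ≈ 39.5 μM —
matching the non-spatial steady states up to the rounding of the calibrated
rate table). The stimulus-triggered influx is active for one minute per
window, placed on interior points within one lattice spacing of the
membrane at heights z ∈ [0.7, 1.0] μm (the postsynaptic-density region is
assumed static); the mask is computed from the membrane at each window
onset and held for the window. A head-size scale factor (initial head
volume over a reference head volume) rescales stimulus delivery; it is 1
for the default geometry. Species are zeroed below z = 0.3 μm (absorbing
boundary standing in for the stable actin rings of the neck base) and at
points farther outside the membrane than 3/β, where the potential has
saturated and fields carry no mass.

## Parameters

Kinetic and mechanical defaults are the calibrated set: k_β = 0.0081 s⁻¹,
I_β = 24.4284, I_S,β = 25.6684 μM/s; k_A = 0.0013 s⁻¹, I_A = 0.0255,
I_S,A = 0.0293 μM/s; k_C = 0.0006 s⁻¹, I_C = 0.0237, I_S,C = 0.4384 μM/s;
k_nuc = 0.0153 μM⁻¹s⁻¹, k_sev = 0.012 s⁻¹, k_n = 0.6 μMⁿ, n = 3.5;
Ψ₀ = 3.6, Ψ₁ = 0.02; ν = 10⁻⁵ μm/s, ξ = 0.1, η = 10⁻¹⁰ μm/(s·pN);
α = 3·10⁴ pN, β = 40; κ = 0.18 pN·μm, ω = 10⁵ s·pN/μm. The scale factors
derive from filament geometry: a ~450-nm dynamic filament at 2.7 nm per
monomer carries 167 monomers (Ψ₀ = 602.214/167 ≈ 3.6) and, at 37 nm
between branches, 12 Arp2/3 (Ψ₁ = 12/602.214 ≈ 0.02; note this equals
0.02, not 0.2). Numerical defaults: Δt = 0.01 s, Δx = 0.0315 μm,
Δs = 0.05 μm at full resolution.

## Resolution presets and cadence choices

Two presets bundle the numerical settings:

* `full` — Δx = 0.0315 μm, Δt = 0.01 s, Δs = 0.05 μm; phases 1 min fixed
  membrane, 3 min coupled pre-stimulus evolution, stimulus window(s), 4 min
  post. Remeshing every 0.5 s; distance field refreshed every step.
* `reduced` — Δx = 0.06 μm, Δt = 0.05 s, Δs = 0.08 μm; phases 10 s / 20 s /
  window / 30 s (~2 simulated minutes for a single stimulus). Remeshing
  every 2 s; distance field refreshed every second step (the membrane moves
  ~10⁻⁴ μm per step, a tiny fraction of Δx). Between full recomputations
  (at every remesh) the signed distance is refreshed exactly only within a
  band of 3/β + 2Δx of the membrane; farther points hold cached values and
  are frozen at zero field regardless.

The reduced preset exists so that a complete coupled run finishes in about
two minutes of wall time on one CPU; every mechanism of the model is
active, only resolution and equilibration lengths are scaled down.

## What equilibrates and what creeps

Basal influx keeps replenishing barbed ends at fixed lattice points; the
membrane recedes from them until the sech² overlap is small. Because the
force decays exponentially with the gap (e-folding 1/(2β) ≈ 12.5 nm), the
outward creep decays only like 1/t and the shape never strictly
equilibrates — the volume keeps growing slowly after the stimulus, as the
underlying model predicts. At reduced scale the 60-s-window baseline creep
is of the same order as the stimulus response, so the scaled-down
experiments are interpreted *comparatively*: all scenarios share the same
deterministic baseline, and the assertions are orderings (control versus
knockout, reduced drag versus control, successive stimulus gains) and
trends, not absolute percentages. Absolute percent changes printed by the
acceptance script at reduced scale are correspondingly larger than
full-resolution values.

## Synthetic fluorescence traces and fitting

The non-spatial sub-model for normalized concentrations (b, a, c), with
steady states (β*, A*, C*) = (3000, 20, 40) μM and basal influx defined as
I = k·(steady state) so the pre-stimulus state is exactly (1, 1, 1), is
linear with piecewise-constant forcing; its closed-form piecewise
exponential is used both as the fitting model and as the oracle for the
RK45 integrator (agreement 10⁻⁶; b(60 s) ≈ 1.4066 at default parameters).
The synthetic generator adds i.i.d. Gaussian noise to the exact response —
it emulates normalized (GFP/RFP-style) concentration ratios with baseline
1, a one-minute rise and exponential relaxation. It does not emulate
correlated acquisition noise, photobleaching, or the bound-versus-free
distinction for cofilin and Arp2/3, so parameter-recovery results bound
estimator behaviour under ideal noise only.

Fitting uses bounded trust-region least squares on the closed form with
multi-starts (log-uniform around the initial guess, plus a no-stimulus
start; equal-cost ties resolve to the smallest inferred stimulus influx,
which handles the degenerate flat-data case). Identifiability at noise
σ = 0.05 with 13 samples differs sharply by channel: the actin and cofilin
responses (amplitudes ≈ 0.41 and 0.65) are recovered with median errors
under 15%, while the Arp2/3 response amplitude
I_S,A/(k_A A*)(1 − e^(−60 k_A)) ≈ 0.085 is comparable to the noise and its
rate constant is recovered only loosely (median ≈ 70%). The aggregate
median error across all six parameters is ≈ 12%.

## Observables

Per output step: enclosed volume and area of Γ; equivalent-area radii of
the z = 0.63 μm (neck) and z = 0.84 μm (head) cross-sections; field totals
both as raw lattice sums and ×Δx³ integrals; summed force-vector norms for
membrane, actin, and their sum; protrusion velocity. Normalized series
divide by the last pre-stimulus sample and include per-volume
("concentration/volume") species curves using the instantaneous volume
(the initial-volume variant is a one-line change; both interpretations are
emitted by normalizing `B_integral` against `volume` or `volume.iloc[0]`).
Force–velocity pairs are recorded every time step — the nonlinearity of
the relation lives at step resolution and a 1-s subsampling smooths it
away; the local force is the mean over the face intersected by the tracked
vertex's displacement ray.

## Known limitations

* No membrane tension or osmotic pressure (volume and area unconstrained);
  no stable actin pool, neck actin rings, or single-filament structure;
  upstream signaling and receptor trafficking are outside the model.
* The reduced preset's actin force scales with Δx (per-point densities are
  resolution-dependent by construction of the divided influx), so absolute
  growth magnitudes are preset-specific; orderings are robust.
* The interface is Lagrangian; self-intersection of the membrane is not
  detected or resolved (not observed in the shipped scenarios).
* Between distance-field refreshes the actin force uses the geometry
  snapshot of the last refresh (at most two steps old in the shipped
  presets).
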