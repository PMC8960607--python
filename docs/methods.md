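# Methods

`ocdsim` couples four sub-models — poroelastic condyle mechanics, a
strain/fluid-velocity mechanoregulation rule, lattice cell-population
dynamics, and phenomenological scaffold degradation — in a daily
iteration. This note records the assumptions, the parameters that
matter, the numerical choices, and what the model does *not* capture.
Units throughout: mm, N, MPa, s (mechanics); days (biology and
degradation); fractions internally, percentages only in reports.

## Geometry and coordinates

The femoral condyle is idealised as an axisymmetric 10 mm × 10 mm block:
articular cartilage (1 mm) at the contact face, subchondral bone up to
the defect depth, cancellous bone above. The cylindrical defect (radius
= depth = 5 mm) opens at the articular surface and is meshed as a
40 × 40 lattice of 0.125 mm square elements; its side wall borders
subchondral bone below and cartilage at the top band, its base borders
cancellous bone. The lattice uses z = 0 at the defect base and z = 5 mm
at the articular surface; the FE model uses a global axial coordinate
with the articular surface at zero (`z_g = depth − z`).

The scaffold is three vertical struts, 0.5 mm thick and 5 mm tall, i.e.
four element columns each (12 of 40 columns → 30 % of lattice elements;
with 50 % material porosity the scaffold material is 15 % of the defect
volume). The strut radial positions are not derivable from the source
geometry; the default centres {1.25, 2.5, 3.75} mm space the struts
evenly away from the axis and the wall and are configurable. The two
outer columns of each strut are *surface*, the two inner ones *bulk*.
Strut top/bottom faces do not erode by default (side faces only).

## Tissue properties

The tissue table stores, per material: elastic modulus, Poisson ratio,
hydraulic conductivity (mm/s), void ratio, grain bulk modulus and cell
diffusion coefficient. Granulation tissue (E = 0.2 MPa, D = 0.8
mm²/day) fills whatever an element's cells, scaffold and formed tissue
do not. The scaffold material: E₀ = 1000 MPa, porosity 50 %
(N₀ = 0.5), permeability 3.63·10⁻⁸ mm/s, cell diffusivity 0.01 mm²/day.
Its Poisson ratio is not tabulated anywhere; the package defaults to
0.3 (typical of rigid synthetic polymers), configurable.

Healthy cartilage is neo-Hookean with C10 = 2.14 MPa and D1 = 0.399.
D1's unit convention is ambiguous in the source table (printed as MPa);
read as the conventional inverse modulus (MPa⁻¹), the small-strain
linearisation G = 2·C10, K = 2/D1 gives E = 10.0 MPa and ν = 0.167 —
exactly the poroelastic-cartilage row — so the MPa⁻¹ reading is adopted
and healthy cartilage is linearised about zero strain (the full
neo-Hookean law is not needed at the strain levels outside the defect).

## Poroelastic finite elements

Biot consolidation at small strain, axisymmetric kinematics,
biquadratic displacement / bilinear pressure (Q9/Q4 Taylor–Hood)
quadrilaterals on a structured grid, 3 × 3 Gauss quadrature, backward
Euler in time, direct sparse LU per phase. The effective-stress
coefficient is 1; specific storage is n/K_f + (1−n)/K_s with porosity
n = e/(1+e), fluid bulk modulus 2300 MPa, and a zero grain bulk modulus
meaning incompressible grains (term dropped). Deriving a Biot
coefficient from the tabulated grain moduli would give α < 0 for
subchondral bone, so α = 1 is also the only self-consistent choice.
Hydraulic conductivity k (mm/s) is converted to mobility k/γ_w with
γ_w = 9.74·10⁻⁶ N/mm³. Transversely isotropic elasticity is
implemented (axial/radial/circumferential convention) for meniscus-like
materials, though the default mesh contains no meniscus.

**Contact idealisation.** The condyle/meniscus/tibial-plateau contact
is replaced by a rigid, frictionless vertical support under the central
contact footprint (default radius 5 mm — the condyle curves away from
the plateau beyond it). A full-width rigid support was tested and
rejected: it displacement-controls the defect through the stiff bone
annulus, suppressing the mechanical stimulus by three orders of
magnitude. An optional Winkler-foundation contact (``support_stiffness``
in MPa/mm) is available but makes the undrained field nearly
homogeneous and is not the default.

**Load case and sampling.** 0.637 MPa is ramped over 1 s on the top
(cancellous) surface with no drainage, then held for 0.5 s of
consolidation with p = 0 along the whole articular surface (the exposed
defect face and cartilage bathe in joint fluid). Per lattice element, γ
is evaluated from the displacement field at the end of consolidation
(the skeleton strain once the surface region has shed its pore
pressure; a compression-end option exists), and v is the maximum Darcy
flux magnitude over the consolidation steps using the element's own
composite permeability. The failure checks read the axial strain at the
undrained compression peak. The FE mesh may be coarser than the
lattice; the default 0.5 mm resolves each strut as its own element
column, and composite lattice properties are block-averaged into FE
cells. A mesh-refinement check (0.5 → 0.125 mm on a hollowed-strut
state) showed no change in the smeared strut strains.

**Verification.** The solver is gated by a patch test (uniform-property
oedometric state reproduced to 1e-8 relative), a drained-column closed
form, and a Terzaghi consolidation benchmark (pore-pressure profile
within 1 % of the series solution at three times).

## Mechanoregulation and cells

S = γ[%]/3.75 + v/0.003 with the half-open class partition
[0, 0.01) resorption, [0.01, 1) bone, [1, 3) cartilage, [3, ∞) fibrous.
Formed bone carries subchondral-bone properties, cartilage the
poroelastic-cartilage row, fibrous tissue its own row.

Cell counts are continuous, capped at 100·(1 − N_scaffold) per element
(50 in an intact strut element, growing as the scaffold erodes). MSCs
enter at the cancellous base, which is held at capacity for the whole
run, and spread by implicit diffusion (zero-flux elsewhere; arithmetic
face diffusivities; the scheme conserves mass with closed boundaries).
Daily update order, fixed by design: differentiate (5 % of local MSCs
into the stimulated phenotype), then mitosis/apoptosis of *pre-existing*
cells (+5 % matching phenotype, −15 % mismatched, −10 % osteoblasts
under resorption), then MSC mitosis (+15 %) limited by the remaining
room, then proportional down-scaling on residual overflow. Initial
seeding fills the base row to the nominal cap of 100 (4000 cells);
the scaffold-reduced capacity binds from the first update.

Homogenisation is the volume-weighted arithmetic average over formed
tissues (cell counts /100), scaffold (weight N_t, modulus channel E_t)
and the granulation remainder (MSCs included), applied to modulus,
Poisson ratio, permeability, grain bulk modulus and cell diffusivity.
Permeability is averaged arithmetically — deliberately following the
weighted-average rule literally rather than the physically more common
harmonic mean. Void ratio is not part of the rule and follows the
dominant species.

## Scaffold degradation

Day convention: iteration d applies the day-d decrement; a milestone
"day X" is the first integer day at/after the continuous crossing
(ceil). On the day a trajectory crosses the erosion-onset threshold
(E_t ≤ 0.1 E₀), the erosion decrement is pro-rated to the post-crossing
fraction of the day — this makes daily stepping reproduce the analytic
calendar exactly (onsets at days 105, 768, 12/23/45; completions at
13/25/50, 115), which is asserted as an oracle-equivalence test for
every preset. Surface erosion carries the unspent part of a day's
decrement into the newly exposed layer, so a two-layer strut finishes
in exactly 2·N₀/k_N days. Erosion and modulus decay run concurrently in
the erosion window; the tabulated presets make E_t and N_t reach zero
together, asserted for all six linear presets. Molecular weight is
never stored; proportionality to E_t is built in. The slow-exponential
preset (k_e = 0.003/day, erosion onset at day 768) reuses the 5 %/day
erosion rate so its calendar is total; the choice is unobservable in
125-day runs. All four laws act uniformly along a strut column, so the
state is stored per column and broadcast to element maps.

## Scaffold stiffness

The standalone scaffold (three concentric rings under 3 % compression)
is a parallel ring-stack: K = Σ_c Ē_c·A_c/L with Ē_c = E_t·N_t per
column, annular areas A_c, and a single calibration mapping the
undegraded state to K₀ = 2445 N/mm (the implied total cross-section,
K₀·L/E_eff,0 ≈ 24.45 mm², is a consequence of K₀ being an input — the
true ring radii are not recoverable). The height average is harmonic
(series springs), which coincides with the arithmetic mean here because
every law leaves columns vertically uniform. Homogeneous degradation
reduces exactly to K₀·E_eff(t)/E_eff(0): 1680 N/mm at day 125 (slow
exponential) and 271 N/mm at day 100 (fast exponential). The uniaxial
model tracks the full 3-D values at day 5 of surface erosion within
0.3 % (1956/2200.5/2322.75 vs 1951/2197/2320 N/mm). An FE cross-check
(homogeneous annular column, ν = 0, RF/Δx = E·A/L within 2 %) guards
the mapping. Surface-erosion and bulk matched-speed trajectories agree
within 2 % of K₀ except during the terminal erosion overlap (days
45–50), where the bulk law's E_t·N_t is quadratic in time while the
surface law stays linear; the analytic gap peaks near 2.5 % of K₀ and
the regression test brackets it at 3 %. Buckling is not part of this
model; slenderness lives in the failure surrogate.

## Failure surrogate

In a contact FE model the collapse of a degraded scaffold appears as
solver non-convergence. The surrogate replaces this with three
configurable checks: (1) solver divergence; (2) a strain cap — any
*load-bearing* scaffold element (E_t·N_t above 1 % of the initial
effective modulus; without the floor, mechanically irrelevant ~0.5 MPa
remnants on the last day of slow bulk degradation would trip it) with
octahedral shear strain above 100 %; (3) empty-shell buckling — once a
strut's interior columns are fully degraded, each surviving contiguous
run of face-sheet columns fails when its height-averaged axial
compression exceeds the Euler strain π²t²/(12L²). The empty-shell gate
is deliberate: interior degradation frees the 0.125 mm face sheets as
independent slender pillars, whereas outside-in thinning (surface
erosion) keeps a contiguous intact core and is treated as stable. With
the default configuration the autocatalytic runs fail on days 14, 26
and 51 — the day after their strut interiors vanish (except slow, one
day later) — while every surface-erosion, bulk and exponential run
completes 125 days. The near-complete-erosion collapse of the *fast*
surface-erosion case seen in fully resolved contact models is not
reproduced: any criterion separating it from the late slow-erosion
state (which must remain stable) would encode solver-specific
behaviour. Exact failure days are generally solver-dependent and only
the qualitative pattern is modelled.

## Problem sizes and determinism

Default runs use the full 40 × 40 lattice with the FE mesh at 0.5 mm
(400 elements, ~3200 unknowns, two sparse factorisations per day); a
125-day run takes ~20 s on one CPU, and the 8 × 8 test fixture (one
two-column strut, rates sped 5×) runs in well under a second per day.
The core loop contains no randomness: identical configurations produce
byte-identical outputs (the configured seed is reserved for
perturbation studies). Outputs are time-series CSV, final lattice grids
(CSV), a JSON manifest embedding the analytic milestone calendar, and
optional legacy-ASCII VTK snapshots written by a minimal in-package
writer.

## What the model does not capture

* No contact, meniscus or tibial plateau in the mesh; the support
  idealisation above stands in for them, and absolute strain levels in
  the defect inherit its uncertainty. Tissue-distribution maps are
  therefore qualitative.
* No pH or degradation-by-product biology; degradation is purely
  mechanical/phenomenological, with a clear-cut surface/bulk split.
* No geometric nonlinearity, post-buckling or remeshing; the failure
  surrogate is a configured criterion, not a bifurcation analysis.
* Equilibrium behaviour: in the slow-exponential run the tissue-class
  area fractions change by ≤ 5 percentage points between days 75 and
  125 (the acceptance suite computes ~3.4), but the late-time
  bone/resorption balance oscillates near the S = 0.01 boundary — a
  property of the threshold rule set, not a numerical artefact.
* The synthetic scaffold is "artificial": one architecture and material
  given all four degradation behaviours in turn, which no single real
  polymer exhibits.
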