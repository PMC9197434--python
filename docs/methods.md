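# Methods

This note records the models behind `hepatrunc`, their assumptions, the
defaults that matter, and what the synthetic scenarios do and do not show
about real patient data.

## Perfusion territories and TPP

Tumor territory is assigned by synchronous multi-source region growing on
a cubic voxel grid: each outlet's terminal centerline points (excluding
the junction point shared with siblings) seed a wavefront; all wavefronts
advance one 6-connected layer per iteration until every tumor voxel is
claimed. Growth propagates through *all* voxels, not only tumor voxels,
because the seeds are vessel-end voxels that generally lie outside the
mask; only tumor voxels count toward the tumor perfusion percentage
TPP(outlet) = 100 × claimed tumor voxels / all tumor voxels. Two choices
are deliberate and configurable in principle but fixed by default:

- **Tie rule.** A voxel reached by several wavefronts in the same
  iteration takes the lowest outlet id. This makes labeling deterministic
  and independent of seed iteration order; it biases ties toward lower
  ids, which matters only on the measure-zero set of equidistant voxels.
- **Grid.** Voxels are half-open cells `[origin + i·h, origin + (i+1)·h)`,
  0-based, single edge length `h` fitted so that the vessel tree, tumor
  and a 10 mm margin fit a cubic `N³` box (default N = 80; the
  patient-scale preset uses 100, which over a ~120 mm domain gives
  h ≈ 1.2–1.6 mm).

Invariants asserted after every run: tumor labeling is a partition, and
ΣTPP = 100% to 1e-9.

## Truncation

Two passes, each an iterative collapse of *terminal junctions* (internal
branches whose children are all leaves):

1. A terminal junction collapses when one of its leaves has
   0 < TPP ≤ 1%. The feeding branch becomes the new outlet with the
   group's summed TPP; it is labeled tumor when that sum exceeds the
   threshold, healthy otherwise. Leaves with TPP exactly 0 are plainly
   healthy and do not trigger this pass — collapsing pure healthy
   junctions is the second pass's job.
2. A terminal junction collapses when all leaves share a tissue label
   (or when a low-TPP leaf remains, resolved by the group-TPP rule);
   mixed tumor/healthy junctions are preserved. Low-TPP leaves that
   survive both passes (protected or lacking cut space) are labeled
   tumor iff the tumoral share of their branch flow exceeds 50%.

Guards: the two most proximal junction levels never collapse
(`protected_levels = 2`; these junctions dominate downstream particle
distribution), and a junction whose feeding branch is shorter than
`min_cut_space = 2 mm` leaves no room for a cut (the criterion is
qualitative in origin; 2 mm is this package's documented default).
Merged outlets are renumbered to the lowest member id. Outlets left
shorter than 5 mm of centerline are extruded along their terminal
tangent to 20 mm so a developed profile can form. Iteration order is
deepest-junction first; because merges involve only sibling leaves the
fixpoint is order-independent. Both passes are idempotent and conserve
ΣTPP and (via member sums) outlet flow.

## Outlet boundary conditions

Healthy flow: segment volumes are literature fractions of the total
liver volume (default table, % of liver: I 2.5, II 7.5, III 9, IV 16,
V 14.5, VI 12, VII 17, VIII 21.5 — round literature-informed values that
sum to 100; override per patient). `Q_s = V_s · k_h` with
k_h = 0.100 min⁻¹; within a segment the flow splits symmetrically at
each junction of the minimal subtree spanning the segment's outlets
(1/2 per bifurcation, 1/3 per trifurcation), giving branching fractions
that sum to 1 per segment. Tumoral flow: `Q_t = V_t · k_c` with
k_c = 0.415 min⁻¹ (tumor tissue's higher metabolic demand), distributed
by TPP. Totals are kept unrounded internally; human-readable reports
round last (135.7 + 128.65 → 264, not 136 + 129 → 265).

The inlet waveform is stored as (time, velocity) samples over one 0.8 s
period and scaled by a single factor so the trapezoidal time-average
volumetric inflow matches the BC total within 0.1%. The synthetic
waveform is a flat diastole at the minimum velocity plus a `sin^q`
systolic pulse (systole ≈ 0.58 s); q is solved so the sampled mean hits
0.121 m/s exactly while the peak hits 0.260 m/s — one closed shape
matching all three stated moments.

## Transport surrogate

The full 3D Navier–Stokes stage is out of scope; transport runs in an
analytic surrogate that keeps exactly the features the hybrid model
relies on:

- **Flow field.** Each branch carries a parabolic (Poiseuille) axial
  profile with no-slip at the wall; its flow is the branch's share of
  the imposed outlet outflows times the waveform shape, so mass is
  conserved at every junction at every instant. Secondary and
  recirculating flows are absent by construction.
- **Rheology.** Simplified Quemada viscosity
  `μ(γ̇) = max{μ0, (√μ∞ + √τ0/(√λ + √γ̇))²}` with μ0 = 3.09e-3,
  μ∞ = 2.65e-3 kg/(m·s), τ0 = 4.36e-3 Pa, λ = 2.18e-2 s⁻¹ (unclamped
  crossover at γ̇ ≈ 253 s⁻¹). The shear rate is the second invariant of
  the rate-of-deformation tensor, which in an axisymmetric profile is
  |∂u_z/∂r|. The rheology enters the particle force closure only; the
  profile shape stays parabolic — a documented simplification.
- **Forces.** Gravity/buoyancy, drag with the Schiller–Naumann factor
  `C_D·Re_p/24 = 1 + 0.15·Re_p^0.687`, the pressure-gradient force
  `m_p (ρ/ρ_p)(u_p·∇)u`, and the virtual-mass force with C_V = 0.5;
  the `du_p/dt` part of the virtual-mass force is moved to the left-hand
  side as an effective mass. Integration is semi-implicit Euler (drag
  implicit), dt = 0.5 ms during accelerating/decelerating waveform
  phases and 1 ms on flat phases (slope threshold 0.5 m/s²); walls are
  specular with tangential and normal restitution 1.
- **Junctions.** The parent exit disk is partitioned into contiguous
  angular sectors ordered by daughter azimuth, each with angular share
  equal to the daughter's flow fraction; a particle keeps its relative
  radius (preserving the normalized parabolic streamfunction) and its
  sector-relative azimuth is stretched over the daughter disk. The map
  is deterministic and makes no claim of 3D junction fidelity beyond
  its flow-split property: uniformly seeded tracers split in proportion
  to flow.
- **Injection and termination.** Planar mode seeds a uniform grid over
  the lumen; catheter mode seeds the 0.7 mm tip disk at 0.12 m/s
  (2.77 ml/min). Bursts every 0.01 s span the third cycle; afterwards
  whole cycles run until fewer than 1.5% of all injected particles
  exited in the latest cycle (strict, checked at whole-cycle
  boundaries), with a configurable cycle cap.

The Stokes settling cross-check integrates the same drag closure in
quiescent fluid at constant μ0 — around a 40 µm sphere the flow is at
the slip scale, where blood is modelled at its high-shear plateau — and
must land within 0.5% of `(ρ_p − ρ) g d² / (18 μ0) = 1.524e-4 m/s`
(the Schiller–Naumann factor at Re_p ≈ 2e-3 costs ~0.2%).

## Release grids, distributions, dose

PRG cells classify on the all-or-mixture rules; the CPRG rule chain is
evaluated in order (tumor/healthy/no-exit constant at >75%, then
tumor/healthy mostly at >50%, then no-value and spatially-uncertain at
>37.5% — no-value wins the 4/8 + 4/8 tie by rule order — else
temporally uncertain); all thresholds strict. CF counts cell-timing
pairs rather than pooling particle fates first, so temporal and spatial
uncertainty stay distinct; spatially-uncertain and empty cell-timings
enter neither numerator nor denominator, and a cell whose particles
exit several same-tissue outlets is not attributable to one outlet and
is likewise excluded. CF aggregates over all bursts of the injection
cycle (not only the 8 CPRG timings). Tumor dose sections are
(2·3+1)² = 7×7 cells; a center cell is admissible iff its full window
contains no no-value cell; sampling is uniform without replacement
(n = 50 by default) with the seed recorded in the result.

## Synthetic scenarios: what they show and what they don't

Generated trees split the shallowest leaf first into 2 (optionally 3)
daughters fanning around the parent tangent with seeded random azimuth;
diameters follow Murray's cube law by default (`d · k^(-1/3)` per
k-furcation, configurable fixed ratio as an alternative). Tumors are
unions of ellipsoids, i.e. peripherally vascularized smooth nodules.
Everything is deterministic per seed.

These fixtures exercise the algorithms' contracts — conservation,
partition, flow-split, rule strictness — at desk scale in seconds to
minutes on one CPU (tracer runs use a few thousand seeds; study-scale
problem sizes are stated in each test). They do not emulate real
hepatic branching statistics, CT noise, skewed inlet profiles,
multilobed or internally vascularized tumors, or progressive
embolization; passing tests therefore validate the implementation, not
patient-specific predictions. Patient-specific headline values from 3D
CFD studies (median tumor doses near 43–45%, sub-percent
truncation-induced distribution differences) depend on imaging data and
full 3D hemodynamics and are outside what this surrogate reproduces.

## Known limitations

- Straight-chord branch frames: curvature within a branch affects only
  its length, not the local profile.
- No particle–particle interaction, Basset history force, catheter wall
  thickness, or saline carrier (catheter fluid is blood).
- Outflow fractions are constant; embolization-induced flow
  redistribution is not modelled.
- The junction sector map is a surrogate; only its flow-split property
  is asserted.
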