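# Methods

This note documents the models behind `aerodose`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a user should know before trusting a number.

## Airway geometry

The lower respiratory tract is an analytic tree of straight circular
tube segments: each segment has a proximal point, distal point and a
constant diameter (mm), daughters attach at the parent's distal point,
and lobes are tagged by descent from the left/right generation-1 branch.
This replaces surface reconstructions from imaging with a representation
that supports exact inside/outside tests for particle-wall contact and
exact morphometry. Single-child segments are allowed so that serial
constrictions and bend joints (used by the extrathoracic surrogate) fit
the same data model; generated bronchial trees are strictly bifurcating.

The generator reproduces the two leading morphometric parameters by
construction: the trachea is built at diameter t_d, and the two main
bronchi leave the carina at half-angles summing exactly to b_a. Deeper
generations follow fixture conventions: daughter diameter ratio 0.78 per
generation (Weibel-like regular dichotomy), segment length 3× diameter,
branching half-angle 35°, successive branching planes rolled by 90°.
These are conventions, not anatomical claims; all are overridable.
Optional volume and total-length targets are met exactly by solving for
the diameter ratio and a global length scale (the volume/length ratio is
non-monotone in the diameter ratio, so the solver brackets every root on
a grid and takes the branch nearest the nominal ratio). Asymmetry
factors perturb daughter angles, diameters and lengths multiplicatively
(seeded, deterministic); at zero asymmetry the left subtree is the exact
mirror image of the right, which the tests use as a symmetry oracle.

"Volume-averaged trachea diameter" is implemented as the length-weighted
mean diameter of generation-0 segments — the weighting is an assumption,
stated here because slice-volume weighting would differ for tapered
tracheas (generated tracheas have constant diameter, where the two
coincide).

Nine phenotype anchors (mean/sd/range of b_a and t_d for clusters
ss…bb) are shipped as fixture data; generated cluster-center trees land
inside the printed ranges by construction.

STL export triangulates each segment as a capped cylinder (watertight
per component). STL import voxelizes the surface, thins it to a medial
skeleton (scikit-image), takes radii from the Euclidean distance
transform and collapses degree-2 chains into segments. It is accurate to
the voxel pitch, erodes roughly one radius at open ends, and is intended
for tube-like surfaces; it is the documented, approximate inverse of the
exporter, not a segmentation tool.

## Carrier flow

The flow model is deliberately reduced-order: quasi-steady per-segment
pipe flow updated from the instantaneous inlet rate. Q(t) = Qmax
sin(2πt/T), defaults Qmax = 90 L/min and T = 2 s (heavy-exercise
conditions; the mean inhalation flow is (2/π)Qmax ≈ 57.3 L/min), or a
steady rate. Junction splits follow Poiseuille subtree conductance
(d⁴/L with children in parallel), so flow conservation is exact at every
junction at every instant. Profiles are parabolic (default) or plug; the
profile integrates exactly to the segment flow. The tracker only asks
the flow provider for a velocity at a point, so a CFD-sampled field
could be substituted without touching the tracker. What this omits, by
design: laryngeal jets, secondary (Dean) vortices, turbulent dispersion,
entrance-length development and any particle back-reaction on the flow.
Deposition numbers from this model are therefore trend- and
benchmark-faithful (see the analytic oracles below), not replacements
for resolved CFD on a specific geometry.

The transitional-turbulence inlet boundary-condition calculators are
provided for setup parity with a full RANS k-ω SST run: k = (3/2)(I·
|u_ref|)², ω = √k/(C_μ^0.25 L), Tu = 100√(2k/3)/|u_ref|, γ = 1 at the
inlet, and the piecewise momentum-thickness-Reynolds-number correlation
with its branch boundary at Tu = 1.3 (the low-Tu branch is used at
equality). The constant is read as C_μ = 0.09 — the standard SST value —
so C_μ^0.25 ≈ 0.5477. These values are reported, not consumed, by the
reduced-order flow.

## Particle transport

One particle per parcel. The momentum balance carries Schiller–Naumann
drag, gravity scaled by (1 − α_p) with the particle volume fraction
α_p = 0 by default (dilute limit), Brownian forcing, and optional
Saffman shear lift and virtual mass (both off by default: the model
lists them, and they matter only marginally for the regimes exercised
here). The Cunningham slip correction is off by default to match the
continuum drag model; a flag enables it.

Drag is evaluated through the finite factor f = C_d Re_p/24 (→ 1 in the
Stokes limit, so no division blow-up) and integrated with an exponential
(point-implicit) update that is exact for constant carrier velocity:
v(t+δt) = u_eff + (v − u_eff)e^(−fδt/τ_p), with the position integral
taken in closed form and u_eff absorbing gravity and the Brownian
acceleration. Because this scheme is unconditionally stable, the
sub-step is set by resolution, not stability: δt = min(flow step,
shortest occupied-segment transit time / 20, a Brownian cap keeping the
rms diffusive step under R_min/30). The relaxation-time cap τ_p/5
sometimes used with explicit integrators is deliberately not applied —
it would make nanometre particles (τ_p ~ ns) intractable while buying no
accuracy for them, since the exponential update lands exactly on the
local equilibrium velocity.

The Brownian force amplitude is √(2 k_B T_o γ_f/Δt) per axis with
γ_f = 3πηd_p the Stokes friction (the reciprocal of the mobility
α = D/(k_B T)). Written with the mobility in the numerator the
expression is dimensionally inconsistent and violates the
fluctuation–dissipation theorem; that variant is retained behind
`printed_mobility_form` for comparison only. With the default form the
free-particle mean-squared displacement is 2Dt per axis exactly, step
size independent.

Wall interaction is stick-on-contact: a particle whose radial distance
reaches the local lumen radius is deposited at the projected contact
point. Segment hand-off interpolates the trajectory to the exit-plane
crossing before testing daughter containment, so classification does not
depend on the sub-step overshoot; where both daughter cylinders contain
the crossing point (the overlap lens at a junction) the particle is
assigned by which side of the carina it crossed on — the earlier
nearest-axis tie-break silently routed the whole core flow into one
daughter and showed up as a spurious lobar asymmetry on mirror trees.
Particles leaving a terminal outlet are escaped (credited to the
unmodelled distal airways by the ICRP correction); particles crossing
the trachea inlet plane are exhaled.

Injection seeds particles on the inlet face, flux-weighted over the
cross-section, at the local fluid velocity, spread uniformly over the
injection window — by default the inhalation half of the second
breathing cycle (the first cycle establishes flow only and is skipped
outright, since the quasi-steady flow carries no history). Sizes come
from the log-normal sampler (count median 0.42 μm, GSD 3.5 — the
"0.42 μm mean" of the source characterization is read as the count
median); density defaults to 4390 kg/m³ (solid iodine aerosol). Run
length defaults to two breathing cycles (4 s of physical time for the
default pattern); the flow step default 0.02 s sits in the 0.015–0.025 s
convention.

The tracker is vectorized over particles (numpy gather by segment id)
and bit-reproducible for a fixed seed. Analytic benchmarks in the test
suite pin the physics: Stokes terminal velocity (1%), drag relaxation
against the closed-form exponential (0.1% at Re ≪ 1), Einstein MSD (5%
at 10⁴ particles), Gormley–Kennedy diffusive tube deposition (10% over
deposition parameter DL/Q ∈ [3·10⁻³, 2·10⁻²]), and laminar horizontal-
tube sedimentation against an independent ballistic quadrature oracle
(10%).

A caution that follows from the geometry model: junction velocity fields
change direction discontinuously, so weak-impaction deposition
(Stk ≲ 0.3) converges toward values below what a resolved bend flow
would give as the sub-step shrinks. The regimes used for acceptance
(Stk > 1 impaction, diffusion, sedimentation) are sub-step converged;
the time-step test halves the sub-step and requires < 1% movement in
nDF in exactly such a regime.

### UA-1 upper-airway surrogate

A serial chain standing in for the mouth-throat path: oral cavity
(12 mm), 90° bend into the pharynx (9 mm), laryngeal constriction
(hydraulic diameter 6 mm), 90° bend into a 6 mm jet section and a final
90° bend into an 8 mm outlet. At 90 L/min the constriction velocity is
≈ 53 m/s and the 10 μm Stokes number exceeds unity, so the fixture
reproduces the inertial filtering of the upper airway (> 90% capture of
10 μm particles), which is the behaviour the acceptance run checks.

## Deposition metrics

nDF credits escaped particles with an explicit ICRP correction factor in
[0, 1]; the factor has no defensible default and must be supplied (it is
a required configuration value). The printed mass convention counts all
escaped mass as deposited; taken literally with no exhaled particles it
would force mDF = 1, so exhaled mass is tracked separately and excluded
from the numerator — the only reading consistent with sub-unity
tabulated values — and a symmetric ICRP-corrected mass convention is
available. The escape credit is a global scalar, not size-resolved; a
size-resolved credit would need the distal deposition model this package
does not contain. Regional fractions normalize lobar stuck amounts by
the lobar total and therefore always sum to 1. The printed per-geometry
table shipped for aggregate checks is reference input (its lobar pairs
sum to 100% within ±0.6 printed-rounding points); the package does not
claim to recompute it, which would require the original imaged
geometries and resolved CFD.

Impaction-parameter curves use d_p in μm and Q in L/min (d_p²Q in
μm²·L/min); when a waveform is supplied Q is its mean inhalation flow.
Points below 0.1 are excluded; the boundary value is retained, with a
1-part-in-10⁹ tolerance so float rounding of d_p²Q cannot drop an
intended boundary point. Histograms are 19 equal bins on [0, 10] μm,
density-normalized; concatenating runs equals the count-weighted merge
of their histograms.

## Cohort clustering

Feature ranking uses a Random-Forest regressor (held-out RMSE reported;
importances non-negative, summing to 1). Clustering is k-means in the
feature space of an RBF kernel, evaluated through the kernel trick, with
k-means++-style seeding in kernel space and a non-increasing objective.
Defaults: z-score normalization per feature (parameters stored), k = 9,
bandwidth from the median pairwise distance heuristic — the procedure's
description names the kernel but neither bandwidth nor initialization,
so both are package choices. Grid labels (s|m|b for t_d) × (s|m|b for
b_a) follow the rank tertiles of the nine centroid coordinates, ties
broken by ascending cluster index; the representative is the member
nearest its centroid in kernel space. Clusters whose representative
distance exceeds a configurable threshold are flagged rather than
dropped, leaving the drop decision (as made for the ss cluster in the
motivating cohort) to the analyst. The synthetic cohort generator draws
subjects from the nine anchors with allometric volume/length scaling and
age/weight increasing in t_d; it emulates the correlation structure that
makes t_d the dominant predictor, not any real population, so ranking
tests on it validate the machinery, not anatomy.

## Grid convergence

Generic NPARC-style verification: observed order from the three-grid
closed form p = ln((f₃−f₂)/(f₂−f₁))/ln r when ratios are common, else a
joint least-squares fit of (f_exact, C, p) — the fit target and norm are
package choices since only "least-squares fit" is specified. GCI =
Fs·|(f_coarse−f_fine)/f_fine|/(r^p−1)·100 with Fs = 1.25; the
asymptotic check is GCI₂₃/(r^p·GCI₁₂) ≈ 1. Because GCI is defined on
the relative error, it is not invariant to shifting f by an offset; the
scaling-law test accounts for the base-value shift explicitly.
Oscillatory grid-to-grid differences raise a dedicated error instead of
reporting a meaningless order. Refinement ratios outside [1.25, 2] warn
per protocol. No CFD lives here; functionals come from manufactured
data or from the tracker's own sub-step convergence.

## Dosimetry export

Deposited particles become point sources: activity = particle mass ×
effective specific activity (mass fraction × pure specific activity;
0.21% × 4.6×10¹⁵ Bq/kg ≈ 9.66×10¹² , reported as 10¹³ Bq/kg at one
significant figure). Activity is mass-proportional across sizes — an
assumption; an equal-split alternative would change per-source weights
but not totals. Each location is duplicated per decay mode (beta and
gamma for ¹³¹I), batches hold at most 500 sources, and batching
conserves count and activity exactly. Beta spectra are carried as
endpoint-energy/intensity triples (0.606 MeV 89.6%, 0.334 MeV 7.34%,
0.807 MeV 0.39%; gamma 0.364 MeV 81.5%); spectral shaping is the
transport code's job. The deck dialect is a documented plain-text format
with a JSON manifest and a lossless parse-back reader; byte-level
compatibility with any licensed transport code is not claimed. Phantom
frames are in cm; the transform is rotation × isotropic scale +
translation with an exact inverse.

## Workflow and reproducibility

`run_pipeline` chains geometry → flow → transport → metrics → export
from one TOML/YAML configuration; every RNG stream derives from the
global seed via `numpy.SeedSequence` spawning, and a rerun with the same
configuration is bit-identical (the report embeds a hash of the
canonical configuration). Stage failures surface with stage-tagged
exceptions; the CLI distinguishes configuration errors (exit 2) from
runtime failures (exit 3).

## Problem sizes

Defaults target statistical sufficiency at interactive cost: acceptance
runs use 5×10⁴ particles for the surrogate deposition check (the
binomial error on a >90% fraction at that count is ≪ 1 point) and 10⁶
sampler draws (0.1% standard error on the geometric mean against a 1%
band); unit benchmarks use 3–10×10³ particles, sized so Monte-Carlo
error sits a factor ≳ 2 under each stated tolerance. The library
default of 10⁵ particles per run (never below 5×10⁴ in study-style
sweeps) matches the statistical convention of the motivating study
design.

## Known limitations

- Reduced-order flow: no turbulence, secondary flows or entrance
  effects; one-way coupling only (no particle feedback on the flow).
- Junction velocity discontinuities bias weak-impaction (Stk ≲ 0.3)
  bend deposition low relative to resolved CFD.
- Straight segments: no curvature between junctions (bend joints are
  piecewise-straight), no non-circular lumens.
- Global, size-independent ICRP escape credit.
- No hygroscopic growth, evaporation/condensation, particle-particle
  interaction, electrostatics or resuspension.
- The skeletonizer assumes tube-like, watertight surfaces and is
  voxel-resolution limited.
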