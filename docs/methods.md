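# Methods

This note documents the models, conventions and numerical choices behind
ribofit, in the order data flows through the pipeline.

## Density synthesis and the fitting force

A simulated map spreads each atom's mass `m_i` (amu) onto the voxel grid
with an isotropic Gaussian kernel. The kernel width follows the map's
nominal resolution `d` through

    sigma = d / (pi * sqrt(2)),

chosen so the corresponding Fourier-space Gaussian falls to 1/e of its peak
at spatial frequency `1/d` — one concrete reading of "resolution defined by
half the width of a Gaussian in Fourier space". The constant is a single
module-level parameter (`density.RESOLUTION_SIGMA_FACTOR`); the CC and
force machinery are agnostic to its exact value, and the self-consistency
tests pin the implementation rather than the convention.

The kernel is truncated per axis to `N_neighbor` grid planes on each side
of the atom (a `(2N)^3` stencil, `N` ∈ {3, 4}; with `N = 4` the CC of a
model against an effectively untruncated synthesis of itself agrees to
four significant digits). Each 1-D factor carries `h / (sqrt(2 pi) sigma)`
(`h` = voxel spacing), so an untruncated single-atom map sums to the
atom's mass.

The fitting objective is minus the non-centered real-space correlation
coefficient,

    CC = sum(rho_sim rho_exp) / sqrt(sum rho_sim^2 * sum rho_exp^2),

over a common grid, with experimental maps clamped non-negative first.
The per-atom force is the exact analytic gradient: `dCC/drho_sim` is
evaluated at the voxels and chained through the Gaussian spreading
weights. The force–gradient agreement with central finite differences
(step 1e-4 Å) is at machine-precision level (~1e-8 relative) because both
sides use the identical truncation stencil; the stencil only changes when
an atom crosses a half-voxel boundary, which a 1e-4 Å step almost never
straddles.

The dimensionless weight `w_EM` fixes the energy weight `k_EM` by force
balance: `k_EM` is chosen so the mean per-atom magnitude of the density
force equals `w_EM` times the mean structural-force magnitude. At
production scale `w_EM` is tiny (1e-7..1e-4) because all-atom forces are
enormous; the toy protocol uses the same controller with bounds
appropriate to its much softer structural potential (0.02..2), and the
controller semantics — double when the largest umbrella-coordinate shift
in a fitting phase was below half the 0.60 Å cap, halve when it exceeded
the cap — are identical.

## Map alignment

Experimental maps are aligned to the model frame in four stages: (1) the
highest-valued voxels whose cumulative volume best matches the molecular
volume are selected (molecular volume estimated as the sum of van der
Waals sphere volumes times a 1.2 packing factor, overridable); (2) the
model is posed into the map by matching centers of mass and principal
inertia axes (density-weighted voxel "masses"), resolving the four proper
sign assignments by CC; (3) the pose is refined by a deterministic
coordinate-wise pattern search over the six rigid degrees of freedom with
shrinking steps (1.0→0.05 Å, 2.0→0.1°), which never decreases CC; (4) the
inverse transform is applied to the map and the result regridded onto a
model-frame grid by cloud-in-cell interpolation (trilinear, exactly
density-conserving).

The inertia stage is a coarse initializer: when the voxel set is cut hard
to the molecular volume its principal axes can deviate tens of degrees
from the atom cloud's, and the CC refinement supplies the remaining
accuracy (round-trip recovery on toy maps is ~0.05° / ~0.03 Å, far inside
the half-voxel contract).

## Dynamics engine and restraints

The engine integrates BAOAB Langevin dynamics in kcal/mol, Å, ps, amu
units (k_B = 1.987204e-3 kcal/mol/K); zero friction recovers velocity
Verlet, verified by energy conservation. The density force is treated as
a slow force and recomputed every few steps (multiple-time-step spirit).
Minimization is steepest descent with backtracking.

Harmonic conventions, deliberately split:

- umbrella / center-of-mass restraints: `V = k |dR|^2` with k in
  kcal/mol/Å², so the standard umbrella constant k = 1.0 is used as-is
  (per-axis equilibrium variance k_B T / 2k, ≈ 0.30 Å² at 300 K);
- steering restraints quoted in pN/Å: `V = k/2 |dr|^2`, so force =
  k·displacement matches the single-molecule convention
  (1 pN = 1.439e-2 kcal/mol/Å, computed from constants, not stored);
- flat-bottom distance restraints are exactly zero inside ±0.1 Å;
  RMSD caps are exactly zero below the 1 Å limit (RMSD against the
  stored reference, no re-fitting).

Every window records its bias spec and umbrella-coordinate series; the
recorded bias energies are recomputable from the samples, which is the
only consistency WHAM requires.

The integrator can remove the system's net rigid-body motion relative to
a reference every few steps (mass-weighted superposition, velocities
rotated along). The window protocol enables this by default: without a
surrounding solvent bath a small bead assembly's global pose random-walks
on the picosecond scale, and production protocols null exactly this
systematic drift.

## Window protocol

One window = EM-fitting phase (density force + optional steering) →
umbrella centers pinned at the current group centers of mass →
equilibration (steering ramped off linearly in four segments) → sampling.
The next window restarts from a configurable fraction (default midpoint)
of the previous sampling phase. The fitting phase is retried with halved
`w_EM` when any umbrella coordinate moves more than the 0.60 Å cap;
persistent violation aborts. The fitting phase runs at higher friction
than sampling: the cap is meant to limit *driven* displacement, and on a
desk-scale system thermal diffusion of a light group's center of mass
over the fitting phase would otherwise consume the whole budget.

Toy phase lengths (defaults: 1 ps fitting, 1.2 ps equilibration, 3.2 ps
sampling per window) are chosen so a full 72-window transition runs in
under two minutes on one CPU; they are orders of magnitude shorter than
production windows, so individual windows are only locally equilibrated
and recovered profiles are qualitative away from well-sampled regions.

## Adaptive path search

Each steered group keeps a moving harmonic target placed `δ` ahead of its
previous-window mean toward the final target (clamped to the target when
the remaining distance is shorter than `δ` — the unclamped rule would
overshoot). After each window the progress projection
`(<r>_n - <r>_{n-1})·û` is compared with `Δ = δ/2`: the force constant is
raised by 25 pN/Å when progress fell short, lowered otherwise, floored at
zero (a negative harmonic constant is unphysical). Way-point lists switch
the final target when all steered groups come within a configurable
radius (default 2 Å) of the current way-point.

The closed-loop validation drives a single bead (20 amu, friction 5/ps,
300 K) across a 5 k_BT double well `a(x² - b²)²` with b = 4 Å, harmonically
confined transverse to the well axis (k_perp = 0.5 kcal/mol/Å² — without
it the unconfined transverse coordinates free-diffuse and a 3-D distance
criterion is meaningless). Window length 16 ps with the mean taken over
the last 12 ps, so the mean-position estimate resolves Δ; the controller
then crosses in ~20 windows for every seed tested, the per-window progress
stays within [0, 2δ] in ≥90% of windows, and the force constant never goes
negative.

## WHAM and projections

The full `(n_biased × 3)`-dimensional WHAM is solved in binless
sample-reweighting form: iterate

    w_s  ∝  1 / sum_j n_j exp((F_j - V_j(R_s)) / k_B T)
    F_j  =  -k_B T ln sum_s w_s exp(-V_j(R_s) / k_B T)

to self-consistency (max |ΔF_j| < 1e-4 kcal/mol; F_1 anchored at zero;
log-sum-exp throughout). Any projected histogram is then a weighted sum —
mathematically identical to histogramming in the full space and then
projecting, without materializing an unstorable histogram. Neighboring
windows whose sampled distributions barely overlap trigger a warning with
the overlap coefficient.

R₁ first rigidly superposes the sample's masked umbrella coordinates onto
the initial reference (unit weight per group — the reference analysis
states the superposition but not a weighting), then projects
`vec(R - Rⁱ)` on the unit vector of `vec(Rᶠ - Rⁱ)`. A frame built with
`ProjectionFrame.from_endpoints` stores the final reference already
superposed onto the initial one, so `R₁(Rᶠ)` equals the full masked
distance and no rigid offset between endpoint structures leaks into the
coordinate. R₂ is implemented as the signed distance of the group from
the initial E-site anchor, positive when the displacement points along
`e_tRNA = unit(r_E^i - r_P^i)` (the P→E translocation direction); the
sign convention at exactly perpendicular displacement takes the positive
branch. Profiles are `-k_B T ln` of the weighted histogram with the
minimum set to zero; empty interior bins are reported as gaps, never
interpolated. Default bin width in R₁/R₂ is ~1 Å, configurable.

## Geometry descriptors

- Ratchet angle: the model is best-fit on the large subunit; the rotation
  best-fitting its small subunit onto the reference small subunit is
  extracted, and its rotation vector is *projected* on the intersubunit
  axis (small-subunit COM → large-subunit COM). Projection (not just a
  sign) makes rotation about a perpendicular axis report ≈0 and fixes the
  sign convention; the synthetic-rotation tests freeze it.
- Head angle: among the three principal axes of the head selection, the
  one most parallel to the travel direction `e_tRNA` is taken, projected
  into the (`e_tRNA`, `e_ratchet`) plane, and the in-plane angle to
  `e_tRNA` measured for model and reference; the reported value is the
  difference, clockwise-positive when viewed from the plane normal
  `e_tRNA × e_ratchet`. Out-of-plane tipping projects away.
- Gate width: `|COM(body nucleotide) - COM(head loop)|` — for the real
  system A790 versus G1338+A1339 of the 16S rRNA, selected by chain and
  residue number as in the deposited structures.
- Screw decomposition: least-squares rotation/translation, converted to
  Chasles form; the axis point is canonicalized to the point on the axis
  closest to the reference centroid (axis points form a line). Rotations
  below 0.1° take a pure-translation branch. Round-trip identity holds to
  1e-6 over (0.5°, 179°).
- Internal/external split: internal = residual displacement after the
  best rigid fit of state A onto state B; external = total − internal.
  Mean displacement magnitudes and internal:external ratios are reported
  per requested sub-selection. Cross-structure atom correspondences are
  caller-supplied; the module does not align sequences.

## Synthetic fixtures

`make_toy_ribosome` builds a two-body bead assembly: a large body (fixed
frame), a small body, an elongated head, two tRNA bead groups with light
"anticodon" sub-groups, and gate analogues (a body-side nucleotide and a
two-residue head-side loop sharing residue numbers 790 / 1338 / 1339 so
chain+residue selections mirror real usage). Defaults — ~550 beads,
ratchet 7°, head swivel 10°, tRNA travel 15 Å, gate opening 8 Å — mirror
the scale of the real transition (intersubunit rotations of several
degrees, swivels of ten-plus degrees, ~15 Å anticodon travel, gate
opening from ~24 to >30 Å). Endpoints are constructed by exact rigid
operations, so the measured descriptors reproduce the spec'd amplitudes
to numerical precision (the construction-measurement round-trip is the
test). The structural potential is a harmonic network: stiff
nearest-neighbor bonds within groups, soft bridges between groups with
rest lengths midway between the POST and PRE distances so the network
favors neither endpoint.

`make_transition_field` supplies the double-well part of the toy
landscape: each moving atom gets a quartic double well along its own
POST→PRE displacement line (minima at both endpoints, total barrier a
stated number of kcal/mol) plus a weak transverse tether that keeps the
path defined. The barrier can be distributed uniformly or proportional to
squared displacement; the transition demo uses the squared weighting so
the far-travelling cargo carries deep wells and is genuinely retained at
the endpoints.

`generate_umbrella_dataset` draws exact Metropolis samples from each
window's biased Boltzmann density on an analytic landscape — deliberately
independent of the dynamics engine, so WHAM correctness is testable
without trusting the integrator. Closed forms used as oracles: for a
harmonic landscape `a x²` under bias `k (x-c)²` the biased density is
Gaussian with mean `kc/(a+k)` and variance `k_B T / 2(a+k)`; a double
well `a (x²-b²)²` has barrier `a b⁴`.

## Transition demo

`demo.run_transition_demo` chains everything: POST-like assembly, PRE
target map (resolution 11 Å, 2.5 Å voxels — experimental-map scale),
squared-weighted transition field (barrier 6 kcal/mol), 72 windows with
the w_EM controller, anticodon steering under the standard constants, and
an RMSD cap anchoring the large subunit (the analysis frame: its
center-of-mass umbrellas cannot restrain internal rotation, and over 72
windows an unanchored frame random-walks far enough to corrupt the CC —
the production protocol's between-window RMSD restraints play the same
role). tRNA groups are not umbrella'd — the displacement cap governs the
ribosome-body umbrella coordinates, as in the reference protocol — but
their centers of mass are recorded as observables and included in the
progress coordinate, which therefore spans the full ~18 Å transition.
Reported CC is measured at the end of each fitting phase (the fitted
model), reaching ~0.99 at the final window; the WHAM profile along R₁
shows both endpoint basins as local minima separated by an interior
barrier.

## What the toy does and does not show

The fixtures validate the machinery — forces against gradients,
estimators against closed forms, protocols against constructed
transitions — on systems whose answers are known. They do not emulate
solvent, electrostatics, an all-atom force field, or production-scale
sampling, so passing tests say nothing quantitative about real ribosome
landscapes; barrier heights in the demo are properties of the synthetic
landscape, not predictions. Window sampling in the demo is far shorter
than its own relaxation times away from the restrained coordinates, so
its profile is qualitative by design.

## Known limitations

- The exact Gaussian-resolution constant and CC normalization follow one
  declared convention each, isolated behind single configuration points.
- WHAM error bars (bootstrap/MBAR-style) are not provided.
- Map I/O assumes orthogonal axes (P1 cell); non-orthorhombic
  experimental maps are out of scope.
- The moment-of-inertia initializer can start the CC refinement far from
  the optimum when the thresholded voxel set is small relative to the
  model; the refinement contract (monotone CC ascent) is what the
  pipeline relies on.
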