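# Methods

`pyfelix` reimplements a FELIX-style multi-lattice autoindexer for serial
crystallography snapshots, together with the synthetic snapshot generator
and evaluation machinery needed to study it without experimental data.
This note records the model, the numerical choices, and what the bundled
simulations do and do not demonstrate.

## The indexing model

A monochromatic snapshot records, for each illuminated crystal, the Bragg
reflections whose reciprocal-lattice points lie close enough to the Ewald
sphere.  Each observed spot is mapped to a scattering vector
`g = k_out − k_in` (beam along +x, `|k_in| = 1/λ`, crystallographic
convention `a*·a = 1`, so `|g| = 2 sin θ / λ = 1/d`).

A single spot constrains but does not determine the orientation `U` of the
crystal that produced it: the rotations mapping a candidate reflection
direction `ĥ` onto the observed `ĝ` form a one-parameter family.  In
Rodrigues–Frank (RF) space, where a rotation by ω about `n̂` is the vector
`r = n̂ tan(ω/2)`, that family is an infinite straight line (a geodesic)
anchored at the minimal rotation `r_min = (ĥ×ĝ)/|ĥ×ĝ| · tan(θ_hg/2)` with
direction `ĥ+ĝ`.  The orientation of every crystal in the image is a point
where many geodesics — one per correctly paired (spot, reflection) —
intersect.  Indexing therefore becomes peak finding in a voxelized
orientation space.

### The four-chart ("frustum") covering

RF space diverges at 180°, so the rotation group is covered by four finite
congruent charts: chart k collects the unit quaternions whose k-th
component has the largest magnitude; local coordinates are the remaining
three components divided by the dominant one, always in [−1, 1]³.  Chart 0
is classical RF space truncated at 90°; charts 1–3 cover near-180°
rotations about axes near x, y, z.  Because a geodesic is a great circle
of the quaternion sphere, its image in every chart is the intersection of
a 2-plane with the hyperplane q_k = 1 — again a straight line.  The four
cube-clipped segments jointly cover the whole projective line, and
boundary continuity across chart faces holds by construction.  This
max-component construction is the single most consequential geometric
choice in the package; any covering with these properties would do, and
published frustum constructions may bookkeep the faces differently, but
the covering (and hence the set of voxels a geodesic can vote in) is
equivalent.

### Ray tracing

Each chart segment is rasterized by exact cell-boundary stepping
(Amanatides–Woo 3D DDA) on an `N_v³` grid, not by point sampling, so visit
counts are deterministic and each voxel is incremented at most once per
geodesic (within one chart a line meets a voxel once; the four chart
interiors are disjoint regions of orientation space).  Counters are dense
int16 by default (4·N_v³ ≈ 216 MB at N_v = 300, 1.7 GB at N_v = 600); a
dict-backed sparse accumulator engages automatically when the dense array
would exceed a configurable memory budget (default 4 GiB, i.e. N_v ≳ 900)
and is verified against the compiled dense path on small grids.  Typical
per-voxel counts in the scenarios here stay in the hundreds, far below the
int16 ceiling; pass `dtype=np.int32` for extraordinarily crowded images.

### Candidate pairing (magnitude window)

A spot with magnitude `|g|` is paired with every reflection family whose
`|h|` satisfies `||g| − |h||/|h| ≤ σ · (σ_2θ/2)/tan θ`, the relative
window obtained by differentiating Bragg's law (`d|g|/|g| = dθ/tan θ`)
with a dimensionless scale factor σ.  The `1/tan θ` growth at low
resolution is essential: under the spherical partiality model an observed
`|g|` differs from its lattice `|q|` by up to the profile radius, and the
window must absorb that.  One geodesic is traced per (g, symmetry-
equivalent reflection) combination — equivalents cannot be collapsed to a
family representative, because different spots of the same crystal select
different orbit members and only the full set produces a common
intersection.

### Candidate extraction and symmetry clustering

Orientation candidates are voxels that dominate their 26 in-chart
neighbours and satisfy `V ≥ max(V_min, f_V · V_max)`.  Because geodesics
are traced for all symmetry equivalents, each crystal appears as up to
|Laue group| equal-height peaks; maxima are therefore greedily clustered
by symmetry-reduced misorientation (tolerance: twice the voxel angular
half-diagonal) before refinement, and the compute cap of 200 candidates
per image applies to clusters, not raw voxels.

### Matching, refinement, acceptance

For a candidate orientation the predicted points `q = U·B·hkl` are matched
to observed spots under three criteria, each isolated in its own function
so it can be swapped independently:

* **magnitude**: `||g| − |q||` within the Bragg-derived window above,
  floored at the profile radius (the partiality displacement bound);
* **ray deviation**: the angle between the outgoing rays `q + k_in` and
  `g + k_in` within `sqrt(σ_2θ² + (σ_η sin 2θ)²)`.  The deviation is
  measured in detector-angle space — where σ_2θ and σ_η are defined —
  rather than between `q̂` and `ĝ` in reciprocal space, because the
  excitation error displaces low-resolution g vectors from their lattice
  points by up to `r_profile/|q|` (several degrees) without moving the
  spot on the detector; a reciprocal-direction criterion would reject a
  large fraction of true matches even for noise-free data;
* **equivalent z-rotation pre-selection**: the residual rotation about
  the lab z axis (configurable to the beam axis) mapping the xy
  projection of `q` onto that of `g` must be below Δω_max.

Assignment is greedy by smallest deviation, one spot per reflection and
vice versa.  Matching is two-stage: a seed match with the deviation bound
widened by the voxel angular half-diagonal (`2√3/N_v`, the orientation
uncertainty of a voxel-centre seed), a Procrustes fit, then a strict
rematch and refit.  Orientation fitting solves the orthogonal-Procrustes
problem aligning unit reference vectors `B·hkl` to observed `ĝ`
(quaternion least squares via `scipy`'s `align_vectors`), iteratively
dropping assignments whose angular residual exceeds
`max(3σ_η, 3·median residual)` for at most 10 rounds — a standard
polycrystal-fitting trim adopted here as the documented stand-in for the
original tool-chain's fitting step, which is published only by citation.

A candidate is accepted if at least `N_min` matches survive and its
completeness — matches divided by the number of predicted recordable
spots (excitation error ≤ r_profile, ray on the panel) — reaches `c_min`.
Duplicates are suppressed in descending n_matched order: a candidate
sharing more than `u_max` of its matched peaks (normalized by the smaller
set) with an accepted solution is dropped.

## Parameters

Per-scenario values below are the published optimal settings for the three
study systems; the remaining knobs are package defaults chosen once.

| parameter | rho-g6 | lysozyme | at1r | meaning |
|---|---|---|---|---|
| N_v | 300 | 400 | 600 | voxels per chart axis |
| f_V | 0.7 | 0.5 | 0.3 | relative visit threshold |
| σ_2θ = σ_η (°) | 0.3 | 0.15 | 0.15 | detector-angle uncertainties |
| d_min (nm) | 0.20 | 0.30 | 0.30 | resolution cutoff |

Defaults: σ (scale) = 0.2, the one published value of the magnitude-window
scale factor, from the experimental configuration of the original study;
V_min = 10 (an absolute floor well above single-voxel noise — the relative
f_V criterion does the real work in clean images); N_min = 10 matched
spots; c_min = 0.5 completeness (the decisive false-positive filter: a
wrong orientation in a crowded image accumulates incidental matches with
completeness ≈ 0.1, a correct one sits near 1); u_max = 0.5 overlap;
Δω_max = 30° (a deliberately loose pre-selection — for a correct match the
equivalent z-rotation is near zero except for reciprocal points close to
the z axis, where it is unconstrained); profile radius 0.0086 nm⁻¹; at
most 200 candidate clusters refined per image.  All angles in
configuration files are degrees; all reciprocal lengths nm⁻¹.

## The synthetic snapshot generator

`simulate_image` draws Haar-uniform orientations (normalized Gaussian
quaternions), predicts every reflection within the resolution cutoff whose
excitation error is at most the profile radius (a hard spherical
partiality model), and places single-pixel spots on a flat square panel
(default 110 µm pixels, 9.55 cm half-extent, matching a typical
large-area detector at the simulated distances).  Optional noise: Gaussian
positional jitter (σ in pixels), uniform random peak loss, and spurious
peaks uniform on the panel.  Spots from different crystals closer than one
pixel are merged into a single peak with dual provenance.  The three named
presets are noise-free, as in the simulation study they emulate; the
dataclass default for custom scenarios is 1 pixel of positional noise.

The generator does **not** model intensities, background, detector tiling
or distortions, bandwidth, divergence, or mosaicity.  Consequently the
bundled tests demonstrate the geometry and bookkeeping of the method — the
RF accumulation finds every lattice, symmetry reduction is correct, the
acceptance filters suppress false positives at 45 lattices/image — but not
robustness to the noise floor of real detectors, to peak-finder errors, or
to unit-cell inaccuracy.  Spot counts per crystal come out within a factor
~2 of the reference study (e.g. ~130 vs 60 for the tetragonal scenario)
because the reference simulation's bandwidth and profile radius are not
published; all internal consistency checks use the package's own forward
model, so this offset affects realism, not correctness.

## Evaluation

Misorientation between two orientations is the minimal rotation angle of
`S·(R2⁻¹R1)` over the proper Laue operators S (one-sided minimization
suffices for a group; orientations are equivalent under right-
multiplication `U → U·S`).  Correctness of an indexed orientation uses a
1.0° symmetry-reduced tolerance by default — far below typical random
misorientations (tens of degrees, e.g. ≤ 62.8° for cubic symmetry) and far
above the ≲ 0.05° error of a correctly refined solution, so results are
insensitive to the exact value across at least 0.5–2°.  Found↔true
matching is greedy in increasing misorientation; with tolerances this far
from the random scale it coincides with optimal assignment.  The random
misorientation baseline is Monte-Carlo (uniform rotation pairs, symmetry
reduced) rather than the closed-form density — identical in distribution
and trivially correct for every Laue class.

## Problem sizes used in the bundled checks

The headline simulation study runs 5 seeded images at 45 crystals/image
for the cubic scenario (~9·10⁴ peaks-pairings, ~2.5·10⁹ voxel visits per
image); single-crystal recovery uses 12 random orientations per scenario;
the cross-symmetry ordering check uses one 20-crystal image per scenario;
the 5-crystal regression uses 6 seeded trials.  These sizes were chosen so
the whole suite completes comfortably on one CPU core while keeping every
statistic's pass/fail margin wide; all of them are plain function
arguments and scale up freely.

## Known limitations

* Unit cells are always given; there is no cell search or refinement.
* Only Laue point-group rotations are used; lattice centering is applied
  as a reflection-condition filter (I: h+k+l even; C: h+k even; ...), but
  other systematic absences (screw axes, glides) are not, so predicted
  completeness denominators can be slightly optimistic for such space
  groups.
* The equivalent-rotation pre-selection axis ("z") follows the lab-frame
  convention of the geometry figure; the original text leaves the axis
  ambiguous, so it is configurable.
* Intensities are ignored throughout; integration, scaling and merging
  are out of scope.
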