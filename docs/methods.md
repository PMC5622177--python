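# Methods

This note records the models, numerical choices and deliberate
simplifications behind `vertefem`, in the spirit of a solver manual: what
is computed, under which assumptions, and what the synthetic tests do and
do not demonstrate about real scan data.

## Units and conventions

Lengths in mm, moduli in GPa, forces in kN: stress × area = GPa·mm² = kN,
so apparent stiffness is kN/mm with no conversion factors anywhere.
Volumes are indexed `data[i, j, k]` with the third index axial
(superior/inferior); voxel indices are 0-based and a voxel centre sits at
`(index + 0.5) · spacing`.

## Image chain

**Normalisation.**  Raw scanner values are truncated at zero and scaled by
`255 / M` to 8-bit grayscale, with `M` either the volume's own maximum or a
fixed `reference_max` shared across specimens scanned under identical
settings.  Both are supported because per-volume scaling maximises dynamic
range while a fixed reference keeps the grayscale→modulus law comparable
across specimens; the pipeline default is the fixed reference (255 for the
phantoms, whose grays are generated on the 8-bit scale).  Wherever
grayscale becomes integer, rounding is half-away-from-zero.

**Cross-scanner conversion** is an affine map `clamp(round(g·v + o), 0,
255)` with gain/offset supplied by configuration.  Deriving the
coefficients (a physical-phantom cross-calibration between scanners) is
out of scope; the map is the hook through which such a calibration enters.

**Down-sampling** to the 1 mm continuum resolution is a fractional-overlap
box filter: each coarse voxel is the volume-weighted mean of the fine
voxels it geometrically overlaps, boundary voxels normalised by covered
volume only.  This partial-volume average conserves mean intensity (to
rounding) and is deliberately not an interpolation: the grayscale of a
coarse voxel should be the bone mass it contains, not a resampled surface.

**Segmentation** thresholds at Otsu's level over the nonzero voxels (or a
user threshold), closes with a ball of configurable radius to merge the
trabecular porosity into a continuum solid, fills holes, keeps the largest
connected component and splits bone from cement at two user-supplied axial
planes.  The plane-based split replaces interactive segmentation — it is
deterministic and scriptable, and for potted specimens the cement/bone
interfaces are very nearly planar.  The closing is padded at the volume
border so foreground touching the boundary (the endcap faces) is not
eroded.

## Mesh and materials

One 8-node brick per labelled voxel, nodes de-duplicated so the mesh is
conforming; element size equals the down-sampled voxel size.  Hex-only
meshing is a deliberate simplification: mixed tet/hex surface meshing adds
geometric fidelity at the boundary but makes stiffness depend on
proprietary meshing heuristics; with voxel bricks the discretisation is
fully reproducible.  Surface staircasing slightly stiffens the boundary,
which is one reason a calibrated α here need not equal one calibrated with
smoothed meshes.

Bone elements follow `E = max(α·GS, E_floor)` with `GS` the element's
(single-voxel) grayscale; cement elements get 2.45 GPa; ν = 0.3 for both.
`E_floor` (default 0.001 GPa) guards against zero-gray elements making the
system singular; it affects only elements that carry essentially no load.
The Abaqus writer groups elements by modulus — exact distinct values when
there are at most 255, otherwise 255 bins mirroring the 8-bit grayscale
resolution.

## Compression solve

Small-strain linear elasticity, trilinear bricks, 2×2×2 Gauss quadrature.
Boundary conditions reproduce the mechanical test: all dofs clamped on the
bottom cement face; the top cement face tied to a rigid plate expressed as
the linearised multipoint constraint `u = u_ref + θ × (x − x_ref)` with a
6-dof reference point — axial translation prescribed (default 1 mm),
lateral translations zero, the three rotations left as free unknowns, so
the plate can tilt as the ball-loaded plate does experimentally.  The
apparent stiffness is the axial reaction at the plate divided by the
prescribed displacement; global equilibrium against the clamped base is
checked to 1e-8 relative.

The kinematics are linear even though a quasi-static geometrically
non-linear solve would be marginally more faithful at 1 mm on ~40 mm
specimens; the geometric correction at 2–3% axial strain is small, and
linearity buys exact superposition (used heavily by the calibration) and
analytic oracles.  A calibrated α therefore absorbs a small systematic
offset relative to a geometrically non-linear solver.

A second boundary mode (`uniaxial`) prescribes only the axial dof on both
faces, leaves lateral motion free and pins rigid-body modes at two nodes
chosen to be compatible with a uniform uniaxial strain field.  In this
mode trilinear bricks represent the constant-strain solution exactly, so a
homogeneous cuboid returns `K = EA/L` to machine precision.  The two-layer
series-spring oracle is run with ν = 0: the series closed form
`K = A / Σ(t_i/E_i)` assumes uncoupled layers, and with ν > 0 the bonded
interface adds a real (physical) lateral constraint that the closed form
does not model.

**Linear solver.**  The reduced system (after constraint elimination) is
symmetric positive definite.  Below 8 000 unknowns a sparse direct
factorisation is used; above, Jacobi-preconditioned conjugate gradients at
1e-9 relative tolerance — for 3-D elasticity the direct factorisation's
fill-in makes it slower than CG well before memory becomes a problem.
Repeated solves at different α during calibration warm-start CG from the
previous displacement field.

## Stiffness extraction

`extract_stiffness` slides a 0.6 mm displacement window one sample at a
time and takes the maximum ordinary-least-squares slope of load against
displacement; windows with fewer than 3 samples are skipped.  Regressing
per window rather than differentiating a smoothed curve is noise-robust
and identical on noiseless piecewise-linear curves; the estimate is
invariant to sample densification and to the displacement origin, and
scales linearly with load.  Sub-micron displacement reversals (machine
jitter) are re-sorted; larger reversals are treated as corrupt data.

## Calibration

The objective is the normalised stiffness RMSE over the calibration group.
Minimisation uses Brent's method (golden section with parabolic
acceleration) on a bounded α bracket, default `(1e-5, 0.1)` GPa per gray
unit — two orders of magnitude around the range of plausible vertebral
values.  If the optimum lands on a bracket end the bracket is expanded one
decade outward once.  FE evaluations are cached per (specimen, α), and the
optimizer trace is part of the result, so the reported optimum is always
the best probed point.

Termination: the primary criterion is the relative x-tolerance on α
(default 1e-5).  Two additional stops are available and recorded in the
result when they fire — an absolute objective threshold (`rmse_stop`,
e.g. 0.1 to accept any fit within 10%) and a relative objective-variation
threshold (`rel_change_stop`).  Both default to off: an absolute stop at
10% would leave α roughly 10% from the optimum on good data, defeating the
recovery accuracy the synthetic studies demonstrate; it exists for
expensive real-data runs where a 10% fit is the acceptance level and
further FE evaluations are not worth their cost.

For models whose stiffness is exactly proportional to α (no fixed-modulus
cement, or cement treated as rigid), the optimum has the closed form
`α* = Σr / Σr²`, `r_i = k_unit_i / k_exp_i`, which the tests use as an
independent oracle for the optimizer.  With real fixed-modulus cement in
series the relation `K(α)` is strictly concave in α (cement compliance
caps the stiffness), so each probed α costs a full solve.

## Morphometry

Run on the high-resolution binary image, not the 1 mm continuum image —
the fabric of individual trabeculae is exactly the information
down-sampling destroys.  The ROI is the largest axis-parallel cylinder
inscribed in the intersection of the per-slice convex supports of the
trabecular mask between the endplate planes (distance-transform maximum).

MIL sampling: a deterministic Fibonacci hemisphere of directions (the seed
rotates the lattice), parallel lines spaced two voxel edges, sampled at one
voxel edge; a crossing is any bone/background change between consecutive
in-ROI samples, and `MIL = total in-ROI line length / crossings`.  The
ellipsoid `nᵀHn = 1/MIL²` is fitted by least squares; MIL eigen-lengths
are `1/√eig(H)`; `DA = 1 − L_min/L_max` (0 isotropic, →1 oriented), and
the trabecular orientation is the angle of the principal eigenvector to
the axial direction folded to ≤90°.  Directions without crossings are
dropped; more than 20% dropped aborts (structure too dense or sparse for
MIL).  For near-ideally oriented structures (parallel plates) the in-plane
1/MIL² values approach zero and the fitted H is numerically semi-definite;
marginally negative eigenvalues (within 5% of the largest) are clamped to
a small positive floor, which caps DA just below 1 instead of failing.

## Statistics

Lin's CCC uses population (1/n) moments, the original definition — worth
stating because group sizes here are small (6–8) and the 1/(n−1) variant
differs noticeably.  Bland–Altman limits use the sample (1/(n−1)) standard
deviation, as is conventional for limits of agreement.  Shapiro–Wilk,
Kruskal–Wallis and the pairwise rank tests are delegated to scipy.  The
between-species post hoc comparison is the unpaired Mann–Whitney rank-sum
test: the groups are independent samples of unequal size, for which a
signed-rank (paired) test is undefined.  Post hoc p-values are reported
raw, without multiplicity correction.

## Synthetic phantom: what it does and does not emulate

The phantom is a cylinder with a solid cortical shell, a trabecular
interior, and uniform cement slabs above and below, on an isotropic 8-bit
grid with additive Gaussian scanner noise.  The trabecular texture is a
correlated Gaussian random field — white noise blurred by an ellipsoidal
kernel whose axial semi-axis is `anisotropy_stretch` times the transverse
one (transverse correlation scale 0.6 mm, a typical trabecular thickness
scale) — thresholded at the quantile that realises the target BV/TV.
This gives continuous, seeded control of the two structural parameters the
morphometry measures (BV/TV exactly by construction; DA monotonically in
the stretch), and grayscale statistics close enough to a real scan to
exercise normalisation, Otsu segmentation and the modulus law.

It does **not** emulate: posterior elements, endplate curvature or growth
plates; marrow with nonzero attenuation; beam hardening or scatter;
plate-like versus rod-like trabecular architecture (the field gives
blob/rod textures); or cortical thickness variation.  Synthetic curves are
toe/linear/plateau with i.i.d. load noise — no hysteresis, no cyclic
preconditioning, no post-yield softening.  Passing the synthetic studies
therefore demonstrates the correctness of the numerical chain and the
identifiability of α under controlled conditions, not the biofidelity of
any particular α value: real calibrated values remain specific to species,
scanner, settings and preparation.

Default phantom: 24 mm diameter, 20 mm body, 4 mm endcaps, 0.5 mm voxels.
Tests and the packaged demo use a smaller geometry (10–16 mm diameter,
7–12 mm body) so that each FE solve stays well under a second and the full
suite runs in minutes; the numbers reported by the acceptance script are
computed at these sizes.  Synthetic curves default to a 0.005 mm sample
step (~20 Hz sampling at the 1 mm/min test speed), a 0.2 mm toe and a
plateau beyond the analysed range.

## Known limitations

- Linear kinematics and hex-only meshing mean a calibrated α is expected
  to differ by a few percent from one obtained with geometrically
  non-linear solves on mixed tet/hex meshes; comparisons of α across
  toolchains must recalibrate.
- The rigid plate is tied, not in contact: it cannot lift off, which
  matters only post-yield — outside the linear regime modelled here.
- MIL numbers depend mildly on direction count and line spacing; defaults
  (512 directions, 2-voxel spacing) are stable to ~0.02 in DA on the
  phantoms, but exact agreement with other fabric implementations is not
  claimed.
- The cement/bone split by axial planes assumes the potting interfaces are
  planar and perpendicular to the loading axis.
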