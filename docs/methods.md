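# Methods

This note records the models, numerical choices and known limitations of
`spihetero`. It is written for someone who wants to judge what the package
computes and what its passing tests do and do not demonstrate.

## Problem setting

Single-particle imaging (SPI) collects one diffraction pattern per particle
per X-ray pulse from a stream of nominally identical nanoparticles. At small
scattering angles each pattern is a flat central slice of the particle's 3D
Fourier intensity at an unknown orientation, sampled with Poisson photon
statistics (here, O(100–1000) photons per frame). When the ensemble is
structurally heterogeneous — the motivating case is gold nanocubes partially
melted by pre-exposure, spanning a continuous cube → sphere transition — the
analysis must characterize the distribution of 3D structures without knowing
either orientations or structures in advance. The package implements two
complementary unsupervised methods plus the simulator needed to test them
with known ground truth:

1. **CLPCA**: EMC classification of frames into 2D class averages, an
   all-pairs common-line similarity matrix over the averages, and PCA of its
   rows into a 3-component structural landscape.
2. **Orientation-conditioned VAE**: per-average orientation and gain
   estimation against a reference cube volume, then a variational
   auto-encoder whose decoder emits octahedrally symmetric 3D intensity
   volumes and whose reconstruction loss compares the Fourier slice at the
   known orientation with the input average. Decoder volumes at any latent
   point are phase retrieved and measured.

## Synthetic data model

**Particle family.** Superballs `|x/a|^p + |y/a|^p + |z/a|^p <= 1`
interpolate between a sphere (p = 2) and a cube (p → ∞). The melting morph
`m ∈ [0, 1]` has two phases, mirroring the physics of surface pre-melting
followed by bulk expansion:

* `m ∈ [0, 1/2]`: exponent falls from the cube limit to 2 at constant
  density 19.32 g cm⁻³ (corners and edges round; volume constant);
* `m ∈ [1/2, 1]`: the particle stays spherical while the density falls
  linearly to 17.31 g cm⁻³ (molten/randomly close-packed gold).

Mass is conserved exactly along the morph (`a(m)` solved in closed form
from the superball volume factor `8a³Γ(1+1/p)³/Γ(1+3/p)`), so the endpoint
volumes differ by exactly 19.32/17.31 = 1.1161: an 11.6% expansion. The
m = 0 endpoint is an exact cube of edge 42 nm; the m = 1 endpoint an
equal-mass sphere of diameter 54.0 nm. A single-phase morph with density
linear in `m` cannot produce the observed two-stage behaviour (shape change
at constant volume, then expansion), which is why the generator separates
the phases.

**Detector.** 6 keV photons, detector 705 mm downstream, central region up
to 1.8° scattering angle, so flat Ewald slices are accurate to ~5×10⁻⁴.
The default working grid covers that angular range with 64×64 pixels, with
a central beamstop disc and one rectangular panel gap in the mask. q is
reported as angular frequency (q = 2πs, nm⁻¹); the edge of the field is at
q ≈ 0.94 nm⁻¹ (≈ 6.7 nm full-period resolution).

**Voxelization and transforms.** Densities are voxelized on odd cubic
grids so the octahedral group acts by exact signed permutations.  Exact
cubes/boxes use a separable exact partial-volume construction (per-axis
box filter); general superballs use exact x-column integration (the
superball's x-extent at (y, z) has a closed form) with midpoint
supersampling in y, z.  The per-axis transfer functions of these
constructions (sinc / Dirichlet kernels) are divided out of the FFT, so
the only discretization error left is grid aliasing; an optional
`refine` parameter voxelizes on a finer grid with the same field of view
and crops the transform, pushing aliases out by the refinement factor
(used when intensities are compared against closed forms, e.g. the sphere
form-factor oracle at <10⁻³ relative error). F(0) equals the particle
mass; mass is conserved along the morph to <0.1% in voxelized form.

**Photon budget of synthetic class averages.** The bootstrapped
classification the data model emulates pools ≈ 0.8 × 2.45M/200 ≈ 9800
frames of 100–1000 photons into each average, i.e. 1–10 M photons; the
generator default is the log-middle, 3×10⁶ photons per average, applied as
Poisson noise on the noiseless slice. Masked pixels carry the noiseless
model value and are flagged, emulating the model-filled gaps of EMC
output. The morph-stage distribution of a real melting ensemble is
unknown; the generator default is uniform occupation of 40 evenly spaced
stages.

**What the generator does not emulate:** Ewald curvature (negligible at
1.8°), detector gain/readout noise beyond Poisson statistics, real panel
layouts, atomistic melting dynamics, beam-profile structure beyond a
lognormal per-shot fluence. Passing tests therefore demonstrate method
correctness under ideal-detector Poisson statistics, not robustness to
instrument systematics.

## EMC 2D classification

Standard Poisson-likelihood EM over hidden (class, in-plane rotation)
pairs with a per-frame scalar fluence. Rotated class models are produced
by bilinear stencils (nearest-neighbour rotation misregisters speckle
minima, which the Poisson log-likelihood punishes catastrophically); the
M-step scatters posterior-weighted photons through the transpose stencils.
Fluence and model updates are coordinate ascent on the EM Q-function, so
with rotations that are exact grid permutations (multiples of 90°) the
total log-likelihood is non-decreasing; with bilinear rotations the M-step
is approximate and monotonicity holds only to a good approximation.

Deterministic annealing (posterior temperature ∝ median photon count,
decayed to 1 over the first half of the iterations) prevents the sharp
likelihood from freezing frames into the arbitrary initial split; models
are initialized from the smoothed dataset mean with small perturbations.
Restarts are compared by final log-likelihood. Empty classes are reseeded
from the worst-explained frame. Pixels never covered by any rotation are
filled from the radial mean and flagged.

Scale handling: multiplying a frame's counts by any constant scales its
fluence estimate by the same constant and leaves its best (class,
rotation) hypothesis unchanged; the posterior distribution itself sharpens
under count rescaling, as it must for any independent-photon likelihood.

## Common-line similarity and CLPCA

Patterns are resampled to polar grids (180 angle bins, bilinear), and full
diameters through q = 0 (half the angle bins, Friedel-glued) are compared
by Pearson correlation over all line pairs, masked samples excluded
pairwise; the similarity of two patterns is the highest coefficient, and
the five radial bins nearest the beamstop are excluded (all diameters
agree trivially at q ≈ 0).

The decisive numerical choice is the correlation domain: **log(1+I)
standardized per radial ring** (angular mean removed, angular spread
divided out with a softening floor of 0.1× the mean spread). Compact
particles concentrate intensity at low q by orders of magnitude, and on
raw or plain-log lines that shared radial falloff pushes *every* pairwise
correlation above ~0.97 — accidental smooth-profile matches then beat the
true common line, and neither planted-class clustering nor the size axis
is recoverable in any photon regime (we measured this, including the
noiseless limit). Ring standardization removes the shared component; the
true common line remains an exact match while unrelated lines become
weakly correlated fringe trains. Size information survives in the
fringe-position structure: for planted spheres of graded diameter one PCA
component correlates with diameter at |Spearman ρ| ≥ 0.8.

The embedding is PCA of the similarity-matrix rows (SVD of the centred
rows; components sign-fixed so the largest-|loading| element is positive;
undefined entries imputed with column means). Isomap, spectral embedding
and t-SNE are available behind the same interface and separate the planted
classes comparably.

One structural caveat found while testing: a *dimer of the primary
particle* shares an exact common line with every pattern of the particle
itself (the dimer's central slice perpendicular to its long axis is the
monomer transform up to scale), so no max-common-line metric can separate
a cube from a dimer of equal cubes. The planted "contaminant" dimer class
therefore uses 30 nm sub-cubes.

## Absolute embedding

Rotation-invariant features: per radial bin, |FFT| of the azimuthal
log-intensity variation, keeping even frequencies (odd ones vanish by
Friedel symmetry) up to a band limit that grows linearly with radius (the
angular Nyquist of the speckle). An MLP with hidden layers 512/128/64/32
(ReLU, Adam, early stopping) maps features to the frozen reference CLPCA
coordinates; features are z-scored and labels standardized internally
with statistics from the training split. Validation MSE is reported per
component on raw coordinates. On the planted four-shape set the per-
component validation MSE is below 25% of the label variance; embedding
displacement under exact in-plane rotation of an input averages ~4% of the
cube–sphere inter-class distance (individual patterns up to ~8%, the
regressor's local roughness at its own noise floor).

## Reference matching (orientation and gain)

Averages are correlated against flat slices of an ideal 42 nm cube volume
over a 600-cell-refined quaternion grid reduced to the octahedral
fundamental domain (de-tuned by a fixed generic rotation so grid points do
not sit on group boundaries; level 20 ≈ 16.8k orientations is the
production default, level 12 ≈ 3.6k the test-scale default). The CC domain
is the same ring-standardized log intensity as the common-line similarity.
The gain G = best/mean CC over the grid is a "cubicness" score: planted
cubes average a distinctly higher gain than planted spheres, and G is
invariant under affine rescaling of the average.

Known limitation: slice planes within a few degrees of one of the cube's
mirror planes have a back-side alias whose reference slice is ≈95%
identical to the pattern; the discrete argmax may land on the alias at any
practical grid resolution. The aliased estimate is pattern-equivalent, so
downstream slice-consistency losses are barely affected.

## VAE

Encoder: dense MLP (256, 64 hidden units) on the normalized pixel vector
concatenated with the orientation quaternion and gain (standardized),
with linear heads for μ and log σ². Decoder: dense MLP (64, 256) from z to
**one value per octahedral-orbit of the volume grid** with a softplus
output; the volume is the scatter of orbit values, hence exactly
octahedrally and Friedel symmetric, non-negative, and ~48× cheaper than a
voxel-wise output layer. The reconstruction compares the trilinear Fourier
slice of the decoded volume at the input's estimated orientation (same
stencil as the simulator) with the input; the loss is
`Σ_px (X′ − X)² + β·KL(N(μ,σ)‖N(0,1))` with β = 1 and a linear warm-up
over the first 30% of epochs, reparameterized sampling, Adam (10⁻³),
mini-batches of 100, all seeded. The networks are authored in numpy with
manual backpropagation.

Inputs are normalized by the dataset-wide azimuthally averaged intensity
(interpolated in log between radial bins), block-binned 2×, and truncated
at the detector-edge q; `generate` multiplies the radial profile back in
(zero beyond the truncation) to give physical-scale volumes.

Decoder grid: 51³ voxels over a 130 nm field of view (voxel 2.55 nm, q
extent 1.21 nm⁻¹). This puts the particle at ~4.5×10³ voxels so that the
downstream 10⁻⁴-of-total-mass density threshold crosses the band-limited
edge near its half-maximum, where the crossing tracks the true boundary
for both cubic and spherical shapes; much coarser grids bias the sphere
volume high (threshold in the edge tail), much finer grids push the
threshold above the density plateau entirely.

Training restarts: a minority of runs settle into a folded latent (two
structural regimes on one latent interval). Final loss does not identify
them; the restart whose latent means correlate most strongly with the gain
(a data-derived quantity) is kept. On the planted melting series the
selected 1D latent orders the morph parameter at |Spearman ρ| ≈ 0.98.

## Phase retrieval and volume measurement

Difference map (β = 1, modulus and support+positivity projections)
followed by error reduction, several random restarts, best-residual
iterate kept, density centred by its centre of mass; gap/beamstop Fourier
samples float freely and are excluded from the residual. Default schedule
at 51³: 100 DM + 50 ER, 2 restarts. The ER residual is non-increasing by
construction. Support: an axis-aligned box, default half-width 28 nm
(holds the 54 nm endpoint sphere, stays under half the 130 nm field).

Volume: count voxels whose density exceeds 10⁻⁴ × the integrated density,
times the voxel volume. For a grid-aligned cube the threshold crossing
moves in whole voxel-layer steps (a ~3% volume granularity at this size);
an optional sub-voxel dithering mode averages the count over a grid of
sub-voxel Fourier shifts, which makes the counting estimator nearly
unbiased on ground truth (cube +0.6%, sphere −1.5%, and flat to ~1%
across the whole constant-volume first half of the morph).

Endpoint estimation along the latent trajectory: the cubic endpoint is
sampled over the stage-1 latent plateau (percentiles 55–95 of the encoded
means on the cubic side), where the generator's particle volume is
exactly constant; the spherical endpoint over the outer 5%. Decoder
rendering artifacts (latent-noise smoothing mixes adjacent shapes, and a
blur in Fourier space damps the real-space density envelope) only
*shrink* thresholded volumes, so each endpoint is estimated as the mean
of the top-3 measurements in its window — the least-degraded renderings —
rather than the window mean. The recovered cube → sphere expansion on the
planted series is 10.6–11.6% across datasets against the built-in 11.6%,
with both absolute volumes systematically ~10% low (decoder blur shrinks
both endpoints; the ratio is what the measurement is for).

## Problem sizes

Defaults used by the test suite and the acceptance script: 64×64 detector,
400–450 synthetic averages over 40 morph stages, quaternion grid level 12,
200 VAE epochs with 2–3 restarts, 51³ volumes, 100 DM + 50 ER phase
retrieval with 2 restarts, EMC at 2000 frames × 32×32 pixels with 16
in-plane rotations. These sizes keep every stage well-behaved on a single
CPU core; all of them are configuration, not constants.
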