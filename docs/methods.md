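# Methods

`idisc` implements the quantitative machinery used to characterize
adhesion/excitability nodes at the cardiac intercalated disc (ID): the
region where cardiomyocytes meet end to end and where the adhesion
molecule N-cadherin and the sodium channel Nav1.5 form interleaved
nanoscale clusters.  No public imaging dataset accompanies the study this
package supports, so every stage is validated on synthetic data with
known ground truth; this note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Coordinate and unit conventions

All physical coordinates are nanometres, origin at the top-left of the
field, x rightward, y downward.  Pixel indices are 0-based; pixel (i, j)
covers the half-open square [j·p, (j+1)·p) × [i·p, (i+1)·p) at pixel size
p (default 20 nm, the reconstruction scale of the super-resolution
images).  Rotations are degrees from +x toward +y.

## Cluster detection and distance statistics (`clusters`)

Reconstructed localization images are mean-filtered (radius 1 px by
default), linearly rescaled to [0, 1] — a deterministic stand-in for the
interactive brightness/contrast adjustment of manual analysis — and
thresholded (fixed level or Otsu).  Connected components (8-connected in
2D, 26-connected in 3D, the defaults of the common particle/object
counters) above `min_size` pixels become clusters with centroid, area or
volume, and circularity 4πA/P² clamped to [0, 1].  Analysis is restricted
to a band of ±500 nm around the ID membrane polyline, the same mask
geometry used on the correlative images.

Edge-to-edge distances between detected (raster) clusters use boundary
pixel centers: minimal pairwise distance minus one pixel diagonal; for
overlapping pixel sets the value is minus the maximal mutual penetration
(Euclidean distance transform).  Parametric ellipse clusters use exact
geometry through a 256-gon approximation whose chord error is below
0.01 nm at cluster scales; the two representations agree within one
pixel.  "Contact" is edge-to-edge ≤ 0.  Nearest-neighbour ties break
toward the lowest reference id.  Distance histograms use left-open,
right-closed 100-nm bins with a contact class, so fractions always sum
to 1.

## Ellipse placement Monte Carlo (`placement`)

Observed two-channel cluster fields are modelled as ellipses in boxes of
(ID line length) × 1,000 nm.  Reference (N-cadherin) ellipses are placed
with uniform center, rotation and sampled size, redrawn on
reference–reference overlap.  Query (Nav1.5) ellipses follow a rejection
scheme with attraction factor f ≥ 1: overlapping proposals are always
accepted, non-overlapping ones with probability 1/f; f = 1 is exactly
uniform placement through the same code path.  For a reference
configuration covering fraction p of proposal space the accepted-overlap
probability is p·f/(p·f + 1 − p), which doubles as an analytic oracle; p
itself is checked by dense grid enumeration.  Ellipse–ellipse overlap is
decided exactly by the conic-pencil characteristic polynomial
(det(λA+B) with interior-negative conics: two distinct positive real
roots ⇔ disjoint), cross-checked against a 64-gon polygonal test.

Open choices, fixed here: ellipse centers must lie inside the box but the
ellipse may extend past its edges; query ellipses may overlap one another
(only reference–reference overlap is forbidden); the rejection cap is
10⁵ draws per ellipse.  The experimental size list is unpublished, so the
default size sampler is log-normal (semi-major median 90 nm, σ = 0.3;
semi-minor = major × U(0.5, 0.9)) and pluggable.  Default replicate count
is 1,000; the validation studies use one 3,000-nm box with 3 reference
and 6 query ellipses, which keeps the model-identification experiment
(100 replicates) within a few minutes on one core.

## Lattice binding walk and Kd readout (`walk`)

A regulator (calmodulin in the worked example) moves on a 6-neighbour
(von Neumann) cubic lattice with 33 nm pitch — the estimated pore-to-pore
distance between Nav1.5 channels — in a cuboid of 32 × 32 × 16 steps
(footprint from the 1,066 nm mean inter-cluster distance; height chosen
so the far boundary does not influence the face).  At 6 µM the cuboid
holds 2,127 molecules, which is also exactly the direct unit conversion
of that concentration over the cuboid volume (`n_ligate_from_concentration`).
44 channels sit on the z = 0 face, either packed into a 7×7 block at
1-site pitch (clustered) or spread on a uniform grid (distributed).

One time step has three phases: (1) every free ligate moves to one of its
in-domain axis neighbours, channel sites weighted by the attraction
factor whether or not the channel is occupied (outward moves are
excluded, which realizes reflecting boundaries); (2) each unoccupied
channel binds the first successful attempt (probability `p_bind` per
co-located free ligate, in index order); (3) each bound ligate releases
with `p_unbind`, staying in place and moving off next step.  A channel
binds at most one ligate; site occupancy is otherwise unrestricted.

Two alternatives were implemented and rejected during development.
Excluding co-occupancy of channel sites makes an interior vacancy of the
packed cluster reachable only from directly above (one entry path versus
about five for an isolated channel) while exit rates stay equal, which
*raises* the clustered Kd — the opposite of the rebinding physics the
simulation exists to expose.  Restricting the attraction to unoccupied
channels removes the cluster-wide attractive basin and leaves the
arrangement contrast in the noise.  With the rules above, the cluster
concentrates free ligates locally and released molecules rebind quickly,
producing a robustly lower clustered Kd.

Kd is read from the equilibrated tail (default: last 40% of the 500
steps; a trace-halves check flags non-stationarity) as
Kd = [free ligate] × (free channels) / (bound channels), concentrations
from counts over the cuboid volume; at half occupancy Kd equals the free
ligate concentration identically.  Because the measured Kd (~110 nM, the
mean of the 88 nM apo and 132 nM Ca²⁺-bound anchors) is far below the
6 µM ligate concentration, equilibrium occupancy is ~98%, and per-replicate
Kd estimates are dominated by the ~1 free channel — hence the paired
(common-seed) design and rank-based comparison.  Calibration scans a
(p_bind, p_unbind) grid on the clustered arrangement at 20 replicates per
point; the arrangement comparison runs 200 replicates per arm (the
full-scale default is 1,000).  The attraction factor default is 4
(dimensionless weight ratio; any value > 1 shows the effect, 4 gives a
clear contrast without dominating the diffusion).

The simulator is validated against exact enumeration: on a 3×3×3 lattice
with two ligates and one channel the full joint Markov chain (783
states) is built phase by phase and its stationary occupancy compared
with long simulated runs.

## Particle averaging (`averaging`)

Co-localized cluster pairs are boxed (100 × 100 px = 2 × 2 µm), binarized
and aligned to their running average: per particle, exhaustive search
over a 2° rotation grid with the translation at the FFT cross-correlation
peak, iterated to convergence, then refined at 0.5° locally.  The score
is the summed inner product with the average, i.e. n·‖average‖²; since
every particle's current pose stays in its search set, the score is
provably non-decreasing (asserted per iteration).  Alignment is two-stage:
rough alignment on the reference (green) channel, transforms applied to
the secondary (red) channel, then a second, narrow-band alignment pass.
Rotation uses nearest-neighbour interpolation on binarized particles
(preserves binarity; bilinear available for intensity data); score ties
under the coarse interpolation break toward the current pose.  The
initial reference is the unaligned mean.  Reference-free alignment fixes
poses only up to a global rigid motion of the consensus frame; recovery
against ground truth therefore removes the estimated gauge (mean rotation
offset, then mean shift offset) before measuring errors, and averages are
registered to the template before correlating.

## CLEM registration (`registration`)

The fluorescence→EM map is affine (six coefficients), estimated from ≥ 3
non-collinear fiducial pairs by least squares on homogeneous coordinates
(`numpy.linalg.lstsq`, i.e. an orthogonal factorization rather than
explicitly formed normal equations, for conditioning).  No robust
weighting: fiducials are assumed hand-picked.  The registration QC flag
defaults to 20 nm RMSE, the mapping error of the super-resolved overlay.

## Surface topology (`topology`)

Height maps z(x, y) on a regular grid are triangulated with two triangles
per cell along a fixed diagonal; the amplification factor is triangulated
area over planform area (≥ 1 by construction; the alternate diagonal
agrees within 0.5% on smooth surfaces, and refinement converges
monotonically).  Peaks are h-maxima (prominence default 10% of the height
range) with greedy minimum-separation filtering (higher peak wins);
nearest-neighbour spacing is reported in 3D and in 2D projection.
Periodicity follows the rendered-spot recipe: projected peaks drawn as
Gaussian spots, 2D FFT, dominant non-DC radial frequency converted to a
period, with a flag when the field spans fewer than two periods.  The
experimental ~6.5× amplification of the plicate region requires the
unpublished segmented volume; the synthetic checks (flat = 1 exactly,
sinusoid with A = λ/2π = 1.216 against quadrature) validate the same
computation.

## Ensemble current model (`current`)

Channels per cluster = cluster area / site area at the 33 nm pore pitch
(square packing by default; hexagonal = √3/2 × denser).  Clusters under a
2 µm patch pipette = π r² × amplification / spacing² (≈ 20 at 6.5× and
1 µm spacing; the experimental estimate ~19 sits between the square and
hexagonal conventions at 1–1.066 µm spacing, so packing and spacing are
explicit parameters).  Peak current I = n_clusters × channels × g × V
with 10 pS × 60 mV = 0.6 pA per channel; the worked example
(19, 44, 10 pS, 60 mV) gives 501.6 pA.

## Synthetic data: what it does and does not emulate

The generators produce elliptical cluster fields through the placement
code path itself (so generated attraction is exact), localization-count
images (uniform points in each ellipse, Gaussian jitter at the stated
localization precision, binned to pixels), fiducial pairs under a known
affine map, analytic height maps, and particle stacks under recorded
poses with additive Gaussian noise.  They do not model blinking kinetics,
PSF shape, detection noise correlations, antibody linkage error, or
drift; consequently the round-trip and recovery tests demonstrate the
correctness of the analysis chain, not its robustness to every artefact
of real SMLM data.  For detection round-trips a well-separated layout
(`min_clearance_nm`, `edge_margin_nm`) keeps ground-truth clusters
distinct and inside the field of view; truncation of edge clusters
otherwise biases centroids, exactly as it would in real images.

## Problem sizes of the validation studies

Placement: contact study 1,000 reps per f; model identification 100
replicates of 10-rep observations against 200-rep model histograms.
Walk: calibration 6 grid points × 20 reps, comparison 200 reps per
arrangement at 500 steps.  Averaging: 10 stacks × 50 particles.
Registration: 100 trials × 20 pairs.  Round trip: 20 seeded fields of 8
clusters.  These sizes keep the whole validation suite within tens of
minutes on a single core while leaving every statistical margin wide.

## Known limitations

- The placement model treats boxes independently and ignores the
  membrane-parallel anisotropy of real ID cluster fields.
- The walk uses discrete synchronous-phase dynamics; rate constants are
  per-step probabilities, not physical on/off rates, so (p_bind,
  p_unbind) are meaningful only through the calibrated Kd.
- Particle averaging assumes a single homogeneous particle class.
- The current model is static (no gating kinetics) and linear by design.
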