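# Methods

## Scope and model

`pnnkit` quantifies perineuronal nets (PNNs) at two scales. At
super-resolution (SIM-like stacks), the WFA-labelled net is reduced to a
3D point cloud of mesh nodes and summarised by five proximity-graph
statistics. At confocal resolution, manually drawn ROI polygons around
individual PNNs support densitometry of the net (mean WFA intensity, PV
co-labelling) and of synaptic puncta (VGAT/VGlut1) inside the ROI. A 2×2
factorial layer (genotype TnC⁺/⁺ vs TnC⁻/⁻ × housing SE vs EE) compares
the per-PNN or per-section measurements across groups.

All distances are physical (µm), derived from the voxel calibration; no
periodic boundaries; intensities live on the 8-bit 0–255 scale.

## Mesh topology

The proximity graph at threshold *t* joins node pairs with Euclidean
distance ≤ *t*. "Connected" means degree ≥ 1 — a per-node property, which
makes the R95 criterion (≥ 95 % of nodes connected) well defined without
reference to components. Defaults:

| parameter | default | meaning |
|---|---|---|
| base threshold | 0.7 µm | edge rule for the four non-sweep metrics |
| R95 start / step / ceiling | 0.7 / 0.05 / 3.0 µm | sweep grid |

The only distance scale stated for this assay family is the 0.7 µm sweep
start, so it doubles as the base threshold; the step is finer than the
SIM lateral resolution. Sweep thresholds are rounded to 9 decimals so the
grid lands on exact decimals (0.7 + 6·0.05 is exactly 1.0); since a node
is connected at *t* iff its nearest-neighbour distance is ≤ *t*, the sweep
is evaluated exactly from the NN distances. "Average distance between
nodes" is the mean **edge length** at the base threshold, not the
all-pairs mean (scale-dominated) nor the NN mean (ignores the mesh); the
graph construction is exposed so either alternative is one line away.
An R95 that never reaches 95 % within the ceiling is reported as NaN with
a reached-flag, and group averages exclude unreached values. "Number of
nodes" is a raw per-PNN count, not normalised by PNN surface area.

Every metric is checked against an independent O(N²) brute-force
implementation (exact edge sets; 1e-9 relative agreement) and under
random rigid motions.

## Node detection

Nodes are diffraction-limited blobs. The detector:

1. matched Gaussian smoothing and negated Laplacian-of-Gaussian response,
   with per-axis sigmas `(σ_lat, σ_lat, σ_ax)` in voxel units taken from
   the expected node FWHM (default: the PSF of the acquisition geometry)
   and the axial/lateral PSF ratio;
2. 26-neighbourhood local maxima of the response;
3. intensity gate: smoothed intensity ≥ raw-stack mean + k·SD (k = 4).
   The raw global mean/SD estimate the background because nodes and
   struts are sparse; the gate is applied to the *smoothed* image, which
   preserves blob peaks (≈ 0.35× amplitude plus neighbour contributions)
   while flattening single-voxel noise. Median/MAD estimators are not
   usable here: zero-clipped read noise puts the raw median at 0 and
   collapses the MAD.
4. ridge rejection: at each candidate, the finite-difference Hessian of
   the smoothed image, rescaled to PSF units, must have all-negative
   eigenvalues with |λ_min|/|λ_max| ≥ 0.35. Genuine blobs score ≈ 0.7;
   maxima riding on mesh struts (elongated structures whose brightness an
   intensity gate cannot separate at high SNR) score < 0.3. This is the
   blob/edge discrimination familiar from SIFT keypoint filtering.
5. greedy suppression of maxima closer than the minimum separation
   (default 0.4 µm), brightest kept, exact ties broken in lexicographic
   voxel order;
6. sub-voxel refinement by a three-point parabolic fit per axis (offsets
   clamped to ±0.5 voxel).

The chain is fully deterministic. On the generator's SIM scenes at SNR 10
it recovers 50–150-node nets with ≤ a few per cent count error and ≈
0.02 µm median localization error (measured by the tests and the
acceptance script, not asserted here).

## Densitometry

**Rolling ball.** The background estimate follows ImageJ's practical
algorithm: for radii ≥ 8 px the image is downscaled (up to 8×), the ball
is rolled on the shrunk image (`skimage.restoration.rolling_ball`), and
the background is upsampled and clipped below the image, guaranteeing
`0 ≤ output ≤ input` and exact zero on constant images. Default radius
50 px, configurable.

**ROI measurements.** Pixel membership is the pixel-centre, even-odd
rule; ROI areas are shoelace × pixel-size². ROIs arrive as files (JSON
polygons or ImageJ `.roi`/`.zip`); they are inputs, not auto-segmented,
mirroring manual delineation. PV classification thresholds each ROI's
mean PV signal at the mean + 3 SD of all pixels outside every ROI.

**Puncta.** Per ROI: threshold, label 8-connected components, filter by
size (default ≥ 3 px), keep components whose centroid lies inside the
polygon (edge-clipped puncta count if their centre of mass is inside),
then report density = count/area (exactly integer × area⁻¹), mean
component area (µm²) and mean pre-threshold intensity. 3D stacks are
quantified on a maximum projection (3D acquisition, 2D particle tool);
per-slice mode is a switch. Two refinements over plain Otsu proved
necessary and are on by default, both configurable:

- *noise floor*: the Otsu threshold on ROI pixels is clamped below by
  median + 4·1.4826·MAD of the same pixels. Otsu always bisects a
  histogram; on a puncta-free ROI it slices through noise and fabricates
  particles. The robust floor is immune to the sparse signal.
- *watershed split*: a distance-transform watershed seeded at distance
  maxima ≥ 3 px apart separates touching puncta before counting — the
  standard FIJI binary-watershed step preceding Analyze Particles.

## Statistics

Per metric: Shapiro–Wilk in each of the four genotype × housing cells at
α = 0.05; any rejection, any constant cell, or any cell with n < 3 routes
to the non-parametric branch (overridable). Parametric branch: two-way
ANOVA with Type II sums of squares (robust to the mild imbalance of 3–4
animals/group) and Tukey HSD over the four cell means. Non-parametric
branch: Kruskal–Wallis H with tie correction across the four cells
(χ², df = 3) and Dunn's pairwise z-tests on mean ranks,
Holm-adjusted by default (none/Bonferroni available). Dunn's test is
implemented in-package (verified against a hand-computed rank example);
everything else delegates to scipy/statsmodels. The statistical unit
follows the assay: per-PNN values for topology and puncta, per-section
means for WFA intensity and counts — explicit in the pipeline
configuration.

## Synthetic data: what it emulates, what it does not

**PNN stacks.** Nodes are placed uniformly on the equatorial band of a
spherical shell (radius default 7 µm, radial jitter σ = 0.3 µm) that fits
inside the axial range — the slab of the net a 52 × 0.125 µm SIM stack
actually captures — with a 0.45 µm hard-core minimum spacing (mesh nodes
are junctions separated by struts; coincident nodes are not physical and
would make counts unidentifiable). Struts join each node to its k = 3
nearest neighbours and are rendered at 0.25× node brightness. Rendering:
Gaussian blobs at the PSF sigmas (0.064 µm lateral / 0.127 µm axial);
noise = Poisson shot noise (gain 50 photons/intensity unit) plus additive
read noise of SD = peak/SNR (SNR default 10 — the paperless free
parameter of the model, set in config, with recovery verified at 5/10/20),
then clipping and 8-bit quantisation.

**Sections.** WFA rings (radial Gaussian annulus inside each circular ROI
polygon), optional PV somata under a configurable fraction of ROIs, and
puncta: per-ROI Poisson counts at the target density, uniform positions
with a 0.6 µm hard-core (synaptic boutons are discrete, non-overlapping
organelles; pure Poisson placement at 0.6/µm² makes ~45 % of puncta
unresolvable at the PSF scale and no counting method could pass a ±15 %
recovery bar), log-normal areas (median 0.15 µm²), truncated-normal
amplitudes, blurred by the lateral PSF. Sections default to a 63×-like
zoomed geometry (0.1 µm pixels, PSF σ 0.1 µm, 7 × 1 µm slices) — the
objective used for synaptic markers; 0.2 µm overview sampling cannot
resolve 0.4 µm boutons 0.6 µm apart as separate 2D particles. The
recorded WFA truth is the realised clean in-ROI mean; puncta truth is the
realised count/size/amplitude, so recovery tests measure the pipeline,
not sampling noise.

**Cohorts.** Each (animal, section) owns an RNG stream spawned from the
master seed via `SeedSequence([seed, animal, section])`, so any subset
regenerates identically. Group effects are multiplicative on any
ground-truth parameter (e.g. node_count × 0.75 for TnC⁻/⁻); log-normal
between-animal variability (CV 0.1) overlays every multiplied parameter.
Cohorts render in two modes: `images` (full rasterisation + detection)
and `summary` (ground-truth node clouds only). Calibration and power
studies use summary mode — the 100-replicate knockout-recovery experiment
(4 animals/group × 3 sections × 5 PNNs) would otherwise need 24 000
rendered SIM stacks — while a separately rendered cohort confirms that
the effect survives the imaging and detection stages, whose count
fidelity the SNR-10 recovery experiments establish independently.

**Statistical units and pseudo-replication.** Topology and puncta
metrics enter the tests per PNN; WFA intensity and counts per section
mean — the convention of the assay family this package implements. With
between-animal variability present (the generator's default CV 0.1),
treating tens of PNNs per group as independent units inflates nominal
significance for factors that vary at the animal level; the full-pipeline
example demonstrates a spurious housing effect arising exactly this way.
A mixed model with animal as a random effect would be the remedy, but is
outside the scope of the implemented analysis; the caveat applies to the
real assay as much as to the simulation.

What passing these tests shows: the algorithms are correct, calibrated
and recover known effects under a realistic forward model. What they do
not show: robustness to structured background (vascular
autofluorescence, tissue scattering), optical aberrations or SIM
reconstruction artefacts, segmentation bias in manual ROI placement, or
biological variance structures beyond log-normal animal effects — none
of which the generator emulates.

## Numerical choices and degenerate inputs

- Empty or constant stacks detect zero nodes (not an error); empty node
  sets yield flagged metric records; graphs with no edges report NaN mean
  edge length.
- `connected_fraction` and `mean_degree` of an empty cloud are 0 with a
  warning; R95 of < 2 nodes is unreached with a warning.
- Node CSV import validates columns and numeric coordinates, reporting
  the offending line number.
- All pipeline CSVs are written with a fixed float format and stable row
  order; identical config + seed reproduces byte-identical outputs.
- Seeds derived from the master seed stay below 2³¹.

## Problem sizes

The test suite and acceptance script use: 200 random clouds (N ≤ 60) for
the brute-force equivalence, 100 clouds for R95 consistency, three SIM
stacks (N = 50/100/150, shell radius 7 µm) for detection recovery, nine
sections across densities 0.1/0.3/0.6 µm⁻² for puncta recovery, 2000
null datasets per statistical route for calibration, and 100
summary-mode cohorts plus one rendered cohort for the knockout
experiment — sizes chosen to give stable estimates at interactive
runtimes on a single CPU.
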