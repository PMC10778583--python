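# Methods

This note documents the models, parameters, numerical choices and known
limitations of `mitomotion`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Input model and calibration

The pipeline operates on single-channel 2-D time-lapse stacks with a spatial
calibration (µm/px) and a frame interval (s). The reference acquisition
regime is a 2-minute sequence of 31 frames, one every 4 s, at 0.2 µm/px.
Conversions between pixel and physical units are exact multiplications;
pixel centers sit at integer coordinates with the origin at the top-left
pixel, x = column, y = row. Calibration comes from explicit arguments or
from TIFF resolution metadata (arguments win); it is never guessed.
Intensities are used comparatively only — no normalization on load, since
detection and segmentation define their own thresholds.

## Drift correction

Slice and stage drift is modelled as a pure per-frame translation.
Sequential estimation (frame *i* vs *i−1*, offsets accumulated to frame 0)
is used rather than all-vs-first because photobleaching makes distant frames
dissimilar. Each pairwise offset maximizes the FFT cross-correlation of the
two frames after (a) cropping border rows/columns that are exactly zero in
either frame — the footprint a previous correction pass leaves — and
(b) Gaussian pre-smoothing with σ = 1 px to suppress pixel noise. The
correlation peak is refined to sub-pixel precision by local matrix-DFT
upsampling (factor 200). A 3-point parabolic interpolation was rejected: its
bias is largest near half-pixel shifts, exactly where a constant drift of
0.5 px/frame puts every pair, and the bias accumulates linearly over the 30
pairs of a sequence. Correction resamples each frame by the negated offset
with bilinear interpolation; out-of-field pixels are zero.

Known limitation: coherently moving objects pull the correlation peak. With
the default scene (30 % movers at 0.25 µm/s among 70 % stationaries) the
accumulated spurious offset stays a few tenths of a µm over 2 min — well
below the 1.5 µm motility threshold — but scenes dominated by movers would
need registration disabled (`run_roi(..., register=False)`). Rotation and
non-rigid tissue deformation are out of scope.

## Spot detection

The detector is a negated, scale-normalized Laplacian of Gaussian with
σ = (d/2)/√2 for nominal blob diameter d (default 1.5 µm), the scale at
which a blob of that diameter is optimally detected; the response is
multiplied by σ². Two discrete-kernel corrections are applied: the kernel's
small nonzero response to constants is subtracted (so flat frames give
exactly zero response), and filtering uses reflect padding. Spots are strict
8-neighbour local maxima with response ≥ the quality threshold; maxima
closer than one blob radius are reduced to the highest-quality one (ties
break toward smaller (y, x)); border maxima whose 3×3 neighbourhood leaves
the frame are discarded. Sub-pixel localization fits the full 2-D quadratic
(including the cross term) to the 3×3 response patch; the separable
per-axis parabola was replaced because rotated elongated blobs showed
worst-case localization errors slightly above 0.5 px.

Quality is the raw response, linear in image intensity, so the threshold is
acquisition-dependent (default 1.0 as a faithful preset; simulator scenes
derive their own operating point, below).

## Tracking

Frame-to-frame linking solves a linear assignment problem exactly
(Hungarian algorithm): candidate pairs are spots within the hard cutoff
(default 2 µm) with cost = squared distance; leaving a spot unmatched costs
cutoff². Because every feasible link (cost ≤ cutoff²) is cheaper than the
two unmatched alternatives it replaces (2·cutoff²), the optimum is the
maximum-cardinality feasible matching of minimal total squared distance —
deterministic and verifiable by exhaustive enumeration on small instances.
Gap closing, splitting and merging are disabled by design: a spot unmatched
in the next frame ends its track, singleton chains are dropped, and tracks
therefore live on strictly consecutive frames with ≥ 2 spots.

Track displacement is the Euclidean distance between first and last
position; mean speed is path length divided by (number of steps × frame
interval), so displacement/duration ≤ mean speed always. The motility
filter keeps tracks with displacement strictly greater than 1.5 µm
("above"). Speed summary statistics run over motile tracks by default
(`speed_on_motile_only`), with the all-tracks alternative exposed, since
the original protocol does not state on which side of the filter speed was
aggregated.

## Morphometry

Morphology is measured on one frame (the first by default). Segmentation
thresholds at Otsu's level or a user-fixed value (foreground = intensity ≥
threshold); connected components use 8-connectivity; holes are not filled.
The area gate [0.2, 5] µm² is inclusive at both ends — the exclusions are
strictly *below* and *above* — with a 1e-9 relative epsilon so areas landing
exactly on a bound survive the float rounding of pixel_size². Feret's
diameter is the maximum pairwise distance over the component's pixel
*corner* points (convex hull first, exhaustive pairwise on the hull), so a
single pixel has Feret √2·px rather than 0. The aspect ratio is
√(λ₁/λ₂) of the unweighted second-moment matrix of the pixel centers with
1/12 px² added to both diagonal terms — the variance of a uniform unit
pixel — which makes an a×b rectangle come out exactly a/b and keeps
1-px-wide components finite.

## Per-ROI metrics

The motile fraction divides the number of motile tracks by the number of
gated first-frame particles (the tracking and segmentation layers count
different objects, so the ratio is clipped at 1 with a warning; an ROI with
zero particles has an undefined fraction, flagged as missing and excluded
from group statistics — never recorded as 0). A per-track denominator is
available as a config option. Summary means/SD/medians are recomputable
from the raw per-track/per-particle tables; SD at n = 1 is missing, not 0.

## Group statistics

The omnibus test is the tie-corrected Kruskal–Wallis statistic
H = [12/(N(N+1)) Σ nᵢR̄ᵢ²] − 3(N+1), divided by 1 − Σ(t³−t)/(N³−N), with a
chi-square upper tail on k−1 degrees of freedom (all-identical data is
defined as H = 0, p = 1). Dunn's post hoc z-tests use ranks computed once
over all groups and the pooled-variance term N(N+1)/12 − Σ(t³−t)/(12(N−1));
the multiplicity adjustment is Bonferroni over the *preselected* pairs only
(p_adj = min(1, p_raw·|pairs|)), matching the practice of comparing each
treatment against a single reference condition rather than all k(k−1)/2
pairs. Per-object observations (tracks, particles) enter pooled across ROIs
— thousands of observations, reproducing the common pseudo-replication
choice rather than correcting it with hierarchical models — while the
motile fraction enters per ROI. The chi-square approximation is trusted for
group sizes ≥ 5.

## Simulator

The simulator renders what the pipeline expects to see, with analytic truth:

* **Geometry** — 500×500 px at 0.2 µm/px (100 µm field), 31 frames / 4 s.
* **Population** — 120 blobs by default, matching the order of magnitude of
  real ROIs (thousands of gated particles across 12 ROIs) while keeping
  trajectories separable; 30 % motile.
* **Shapes** — rotated anisotropic Gaussians whose half-maximum contour is
  an ellipse with semi-axes a ∈ [0.5, 0.9] µm, b ∈ [0.25, 0.4] µm, giving
  analytic area πab (≈ 0.4–1.1 µm², inside the gate), Feret 2a, aspect a/b
  — sizes and elongations typical of neuronal mitochondria.
* **Motion** — movers travel at 0.25 µm/s along a per-blob constant random
  heading (analytic displacement = speed × duration = 30 µm over a full
  sequence; headings are rejection-sampled so the whole path stays in the
  field), or optionally as a reflected random walk. Stationaries jitter
  with 0.02 µm/frame. Whole *trajectories* keep a minimum separation
  (3 µm default) so tracks never cross and linking can be scored exactly.
* **Degradations** — global constant drift (px/frame), exponential
  photobleaching of the signal (half-life 30 frames), Gaussian noise with
  SNR = (peak − background)/σ_noise = 10.

Identical seeds give byte-identical movies and truth tables. What the
simulator does **not** emulate: optical PSF structure, fission/fusion,
track crossings, local tissue deformation, non-Gaussian noise, and
foreground clutter (axon bundles, out-of-focus light). Passing tests on
these scenes therefore demonstrate the correctness of the computational
chain under the stated regime, not segmentation robustness on real tissue,
where thresholds must still be adjusted by the operator.

Scene-derived analysis preset: segmentation threshold = background +
intensity/2 (the analytic half-maximum level, standing in for the manual
adjustment of real data), and quality threshold = max(0.15 × bleached peak,
5 × the detector's noise-response SD, computed as noise σ × the L2 norm of
the normalized LoG kernel). Both follow from scene parameters, not from any
measured outcome.

## Validation problem sizes

The acceptance script uses: 200 random frame-pair instances (≤ 6 spots each)
against exhaustive enumeration; one 31-frame drift scene at 0.5/−0.3
px/frame; one 20-blob SNR-5 detection scene (bleaching disabled so the
stated SNR holds in every scored frame) scored on every 5th frame; ten
31-frame scenes at true motile fraction 0.30; ten rotations of a 3×1 µm
ellipse plus 100 random components for Feret; 1000 null simulations
(3 groups × 12) for the type-I error of the omnibus test; and a
4-condition × 3-ROI batch (256 px, 13 frames) rerun twice and compared
byte-for-byte. Smaller fields/sequences in the batch scenes keep the full
study cheap to regenerate; all recovered-quantity checks use full
study-condition scenes.
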