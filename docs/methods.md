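# Methods

`hubkin` quantifies how a transcription factor (TF) occupies its genomic
targets in live embryos: how long individual molecules stay bound to
chromatin, how they explore the nucleus, how the TF's transient high-local-
concentration accumulations ("hubs") form and persist, and how often those
hubs visit a transcribing locus. Because the raw light-sheet and
single-molecule microscopy such analyses consume is rarely shareable at
desk scale, the package pairs every analysis with a seeded synthetic-data
generator whose ground truth the analyses are validated against.

## 1. Single-molecule residence times (500 ms cadence)

**Model.** At long (500 ms) exposures only chromatin-bound and slowly moving
molecules survive localization, so the distribution of track durations
reports unbinding kinetics convolved with photobleaching and tracking loss.
The survival probability of track durations is fit with a double
exponential

    S(t) = F·exp(−k_ns·t) + (1 − F)·exp(−k_s·t),

where `k_ns ≥ k_s` are the fast (non-specific) and slow (specific) apparent
off-rates and `F` the fast fraction. The slow rate is biased upward by
photobleaching and chromatin motion; both are measured on a histone control
(stably incorporated, effectively never unbinding) imaged identically, whose
slow rate defines `k_bias`. The corrected residence time is
`1/(k_s − k_bias)`, with its standard error from first-order propagation of
both fits' parameter errors.

**Estimator choices.**

* Survival is the empirical complement-CDF of track durations on the grid
  of observed unique durations; durations below 2 s are excluded before
  normalization (removing tracking errors and slow diffusers) and grid
  points with `S < 10⁻³` are excluded from the fit range.
* The fit is weighted nonlinear least squares with weights `w ∝ 1/S`. This
  both emphasizes the tail (so the slow rate is estimated properly) and
  matches the binomial variance of the empirical survival,
  `Var Ŝ ≈ S/n`. Weights are floored at grid points supported by fewer
  than 10 tracks so a handful of extreme-tail tracks cannot dominate the
  objective.
* The model is evaluated on the shifted axis `t′ = t − t_min`, where
  `t_min` is the first grid point (where `S = 1` by construction). For
  exponential mixtures the shift is exact by memorylessness; without it the
  constraint `F + (1 − F) = 1` cannot represent a thresholded curve whose
  amplitude at the origin exceeds 1, which biases `k_s` downward. For
  curves starting at `t = 0` the shift is a no-op.
* Initialization is multi-start from five log-spaced `(k_ns, k_s)` pairs
  bracketing the gross decay rate; the best weighted SSE wins, and
  `k_ns ≥ k_s` is enforced by ordering (swapping `F ↔ 1 − F`).
* **Identifiability collapse.** Two exponentials closer than a factor
  `ratio_min = 3` in rate are not separable on a finite noisy survival
  curve; an unconstrained fit then splits a single decay into two arbitrary
  nearby rates and `k_s` becomes a coin flip. When the best double fit
  lands in that regime (or pushes `F` to a boundary), the fit collapses to
  the single-exponential model and flags `collapsed_single`. On noiseless
  genuinely two-component curves the collapse never triggers, and the fit
  agrees with an independent dense grid-search oracle to < 10⁻³ relative
  error.

**What the generator emulates.** Bound molecules end their track at the
earlier of exponential unbinding and exponential photobleaching (the
censoring the `k_bias` subtraction corrects); the censoring cause is kept in
the ground truth. Non-bound molecules are lost at faster rates. Track
durations are `n_frames × Δt` with `n_frames = ceil(T/Δt)` and a 2-frame
minimum, which preserves the exponential rate exactly on the duration grid.
It does not emulate defocalization kinetics, blinking, or exposure-time
motion blur; a real 500 ms acquisition removes fast molecules by blur,
whereas the generator simply assigns them short observation spans.

Validation recovers a 5 s bound residence within 15% from 5,000 simulated
tracks (0.2/s unbinding, 0.1/s bleaching, a 0.5 s-dwell non-specific
population, and a histone-like control) across seeds.

## 2. Fast tracking: diffusion bins, clusters, anisotropy (~12.5 ms cadence)

**Diffusion assignment.** Each track's likelihood is evaluated on a
100-point log-spaced grid of diffusion coefficients D ∈ [0.01, 100] μm²/s
under 2D Brownian motion with per-axis jump variance
`2·(D·Δt + σ_loc²)`, normalized into a per-track occupancy vector, and the
assigned coefficient is the occupancy-weighted geometric mean
`exp(Σ occᵢ · ln Dᵢ)`. This is a deliberate desk-scale simplification of
variational state-array inference: the same occupancy-weighted geometric-
mean assignment, without the variational model-selection machinery or
localization-error marginalization. An optional one-pass empirical prior
(the average of normalized per-track likelihoods) can pool strength across
tracks; it is **off by default** — on well-separated three-state synthetic
data the shared prior concentrates mass at the dominant (bound) mode and
drags boundary-adjacent intermediate tracks below the bound threshold,
worsening bin recovery.

Tracks are segregated into kinetic bins at the conventional thresholds:
bound `D ≤ 0.08`, intermediate `0.08 < D < 0.5`, free `D ≥ 0.5` μm²/s.
Note that the bound/intermediate boundary sits near `σ_loc²/Δt`
(≈ 0.07 μm²/s at σ_loc = 30 nm, Δt = 12.5 ms): below this, localization
noise dominates the jump variance and D is only bounded from above. The
synthetic defaults use σ_loc = 20 nm, appropriate for bright
photoconvertible tags, where three-state recovery is within ±2 percentage
points at 2,000 tracks (the acceptance band is ±5).

The fast frame interval defaults to 0.0125433 s.

**Clustering.** Mean track positions are clustered with DBSCAN
(ε = 0.2 μm, min 10 points). The package implements the deterministic,
permutation-invariant variant: clusters are connected components of the
core-point ε-graph, and border points join their *nearest* core point (ties
broken toward the lexicographically smaller coordinate). Textbook DBSCAN
assigns border points by visit order, which is not permutation-invariant;
the nearest-core rule is the tie-break that makes the partition a function
of the point set alone. The suite checks exact agreement with an
independent O(n²) brute-force oracle and label equivariance under input
permutation.

**Anisotropy.** For each pair of consecutive jumps both ≥ 0.2 μm (repeated
coordinates count as zero-length and are excluded), the angle between the
displacement vectors is recorded in [0°, 180°] (0° = forward continuation,
180° = reversal). The fold-anisotropy is
`P(angle ∈ [150°, 180°]) / P(angle ∈ [0°, 30°])`; values above 1 indicate
compact, revisiting exploration. Bound-bin tracks are removed first (a
stationary molecule's angles are localization noise); "in clusters"
restricts to tracks whose mean position belongs to a DBSCAN cluster. On
simulated free diffusion the statistic is 1.00 ± 0.05 at 10⁴ angles; a
0.3 μm reflecting trap raises it above 1.2 (in practice ≈ 5–7: nearly
every ≥ 0.2 μm jump inside a 0.3 μm trap involves the boundary).

**Error bars** use half-sample subsampling: the statistic on 50% of the
data, 20 times, reporting the replicate standard deviation.

## 3. Hub segmentation and occupancy

Each nucleus is normalized to its mean intensity, so voxel values read as
fold enrichment. Hubs are segmented per nucleus per frame:

1. 3×3×3 median filter (noise removal);
2. grayscale erosion with an ellipsoidal footprint (2 voxels laterally,
   1 axially — hub scale is 0.3–1 μm at 0.108/0.3 μm voxels);
3. morphological reconstruction by dilation of the eroded image under the
   median-filtered image (opening by reconstruction);
4. subtraction of the reconstruction, leaving compact bright peaks;
5. threshold of the residual at 2× its robust (MAD-based) σ inside the
   nucleus — reconstruction-subtraction leaves near-zero background, so a
   noise-scaled threshold is stable; a 10⁻⁶ floor handles noise-free input;
6. local-maxima markers (minimum lateral separation 3 voxels, preventing
   over-splitting of amorphous hubs) and marker-controlled watershed within
   the binary mask, separating fused hubs across saddles;
7. region properties; regions smaller than 4 voxels or with mean
   enrichment < 1.4× the nuclear mean are discarded. The 1.4 default is
   the published CDF-derived operating point for this assay family; it is
   configuration, not recomputed from the data.

Everything outside the nucleus is set to the in-nucleus mean before
filtering so the nuclear boundary produces no morphological residual. The
nuclear volume fraction occupied by hubs is the ratio of in-nucleus hub
voxels to nucleus voxels; raising the enrichment cutoff can only shrink
hub count and volume fraction (checked as a monotonicity property).

Nuclei come either from ground-truth label maps (synthetic data) or from a
threshold fallback (anisotropic Gaussian smoothing, Otsu, hole filling,
components) that achieves Jaccard ≥ 0.9 on synthetic ellipsoids — a stand-in
for learned segmentation models, which are out of scope. Nuclei are tracked
across frames by gated nearest-neighbour centroid matching
(gate 1 μm/frame); an over-gate jump terminates a track rather than
swapping identities.

## 4. Hub lifetimes by intensity autocorrelation

Hub identity is deliberately *not* tracked over time. Instead, after
trimming 20 frames at each end of a nuclear cycle (chromatin reorganization
phases), the movie is cut into consecutive 20-frame intervals
(≈ 110 s at the 5.53 s volumetric cadence). At each interval start every
segmented hub seeds a 1 μm³ box; the box centre follows its nucleus's
centroid displacement frame by frame. The mean normalized signal in the box
gives a 20-sample series whose mean-subtracted, lag-0-normalized (biased,
1/N) autocorrelation is smoothed with a Savitzky–Golay filter (window 7,
order 2) — excluding lag 0, whose noise-variance spike would otherwise
bleed into the first lags — and the first zero-crossing, linearly
interpolated between bracketing lags, is the hub's lifetime in seconds.
Series that never cross are censored at the maximum lag and flagged; the
autocorrelation of the normalized (not raw) signal is used.

**Finite-window bias.** The zero-crossing of a windowed autocorrelation
estimator is *not* the asymptotic closed form unless the window is much
longer than the signal's correlation time: a cosine of 40-frame period
crosses at ~9.7 frames in a 160-frame window (quarter-period 10) but at
~7.1 frames in a 20-frame window, for every standard ACF normalization.
Zero-crossing lifetimes from 20-frame intervals are therefore a
*relative* persistence measure — monotone in the true on-time (rank
correlation > 0.95 on a 5/15/30/60 s ladder) but compressed at the long
end. Comparisons across conditions measured with the same window are
unaffected; absolute lifetimes are not claimed.

**Short/long classification.** Log zero-crossings of uncensored hubs are
fit with a two-component Gaussian mixture by EM; each hub is classified by
posterior ≥ 0.5 and the long-lived fraction reported (with per-replicate
std when replicate labels exist). Component standard deviations are floored
at 0.3 log-units — the measurement resolution: crossings are quasi-discrete
near one frame, and an unconstrained EM collapses onto the spike of
identical one-frame values. A BIC comparison against a single Gaussian
flags effectively unimodal inputs (`single_population`). On a 50/50
mixture of 5 s and 60 s exponential on-times the long fraction is recovered
within ±10 points; for strongly imbalanced mixtures (e.g. 80/20) the
minority fraction is overestimated by up to ~15 points because the short
class's heavy upper tail overlaps the long mode after the crossing
transform — a known limitation of this classifier, not of the lifetime
measurement.

Condition comparisons subsample each condition to 100 hubs, then apply
Kruskal–Wallis followed by pairwise two-sided Mann–Whitney U tests.

## 5. Hub–locus interactions

The transcription site (an MS2/MCP spot in channel 2) is detected per frame
with a difference-of-Gaussians band-pass and a percentile threshold over
in-nucleus voxels (default 99.8 — the threshold percentile is
instrument-dependent and therefore configuration); the brightest surviving
component per nucleus is the site, sites within 0.6 μm of the nuclear
boundary are rejected (bright-nucleus/dark-cytoplasm edge artefact), and
interior dropped frames are filled by linear interpolation.

Because hubs are amorphous, interactions are called from mask overlap, not
centroid distances: a frame interacts when any segmented hub voxel lies
within a 0.5 μm-radius sphere of the site, evaluated in physical units with
anisotropic voxels (a voxel-radius sphere would be anisotropic in μm), in
3D. Events are maximal runs of ≥ 2 consecutive overlap frames (≈ 11 s at
the 5.53 s cadence — single-frame overlaps are treated as random
fluctuations); durations (`n_frames × Δt`) are categorized short (< 15 s),
middle ([15, 55] s — the boundary values are assigned to the middle class)
and long (> 55 s). Per-nucleus frequency is events per minute of
transcriptional activity (first site detection to the last analysed frame),
classed at 0.5/min.

Specificity is assessed against three random control spots per nucleus,
placed by rejection sampling at exactly 1.5 μm from the site in uniform
random directions, each with a 0.6 μm radius fully inside the nucleus
(checked against the anisotropic distance transform) and pairwise
non-overlapping; control statistics are averaged over the three spots
before comparison. Radial enrichment profiles are computed in a
1.1 × 1.1 μm lateral window on the z-plane nearest the site, averaged over
frames, with the summary value the mean within 0.55 μm.

On synthetic movies with prescribed events, noise-free recovery is exact
(every event within ±1 frame, no spurious events), recall ≥ 0.9 under
Poisson noise at hub SNR 5, and the prescribed 0.5/min frequency is
recovered within 15%.

## 6. Synthetic data: what it does and does not emulate

The generators produce, deterministically per (seed, config):

* **Track tables** — per-state 2D Brownian displacements
  (variance `2DΔt` per axis) plus independent localization noise;
  bound-state termination by competing unbinding/bleaching exponentials;
  optional Gaussian spatial clustering of bound tracks; a reflected-walk
  variant for confined diffusion.
* **Hub movies** — uniform-intensity ellipsoidal nuclei (optionally with
  rigid slow translation, to exercise motion-adjusted boxes and nucleus
  tracking), hubs as 3D Gaussians of prescribed amplitude present between
  birth and death frames, lifetimes from a two-component exponential
  mixture; Poisson or Gaussian noise applied last.
* **Two-colour locus movies** — one diffraction-limited spot performing a
  small random walk well inside the nucleus; during each prescribed event a
  hub Gaussian sits within 0.5 μm of the locus for exactly the prescribed
  frames; decoy hubs keep ≥ 1.6 μm away so noise-free movies contain no
  spurious overlap. Event counts follow `round(frequency × minutes)`.

Not emulated: PSF anisotropy and excitation-pattern structure, camera gain
maps, exposure-time motion blur, chromatin polymer motion, hub merge/split
lineage, nuclear divisions. Passing tests therefore demonstrate the
*estimators* are correct under their stated models at realistic sizes and
noise levels — not that the models capture every property of real embryo
data.

## 7. Problem sizes and numerical conventions

Validation sizes: 5,000 tracks per condition for residence
recovery; 2,000 tracks for kinetic bins; ≥ 10⁴ angles for the isotropy
null; 50 instances ≤ 500 points for the clustering oracle; 120 hubs for
the lifetime-mixture recovery; 12–30 single-nucleus movies of 131 frames
(12 min) for interaction recovery; 1,000 seeds for the control-spot
contract. Movies use (z, y, x) voxels of (0.3, 0.108, 0.108) μm and the
5.53 s volumetric cadence.

Conventions: time is 0-based frame index × frame interval; coordinates are
continuous μm with origin at the stack corner, voxel indices 0-based;
movies are TZYX TIFF, track tables CSV
(`track_id,frame,x_um,y_um,intensity`), ground truth and reports JSON. All
stochastic steps derive their RNG from the master seed and a stable stream
label (CRC-based, process-independent), so every artefact is byte-identical
across reruns of the same configuration; output paths are excluded from the
config echo so artefact identity does not depend on where a run is written.
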