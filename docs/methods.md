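# Methods

## Image model and coordinate conventions

A recording is a single-channel stack of shape (t, y, x) in
single-precision-compatible floats, with physical pixel size (µm/px) and
frame interval (s) supplied by the user; TIFF header text is stored
verbatim but never parsed for scaling, because scaling calibration is a
per-setup measurement. Pixel indices are 0-based and coordinates are
(x, y) = (column, row); centres of mass and contour points are sub-pixel.

## Motion correction

Frames are registered to a reference frame by rigid translation. The
shift estimator is phase cross-correlation (scikit-image), integer-pixel
by default with optional 10× upsampled subpixel refinement; it is
exposed as a pluggable callable so another engine can be substituted
without touching the pipeline. Translated-in pixels are filled with the
frame median, which is neutral for later averaging. Registration is
deliberately simple: it is preprocessing, not the analytical
contribution, and rigid translation is the dominant motion mode in the
short recordings this tool targets. The pipeline registers before
background subtraction (the order is fixed in the CLI); since the
background correction is a per-frame scalar, the order only affects
pixels near the frame edge.

Featureless frames (zero variance) cannot be registered; they get shift
(0, 0) and a warning.

## ROI detection

The discrete Laplacian uses the 4-neighbour kernel (centre −4, N/S/E/W
+1) — the direct second-central-difference discretisation of
∂²/∂x² + ∂²/∂y² — with replicate edge padding so image borders do not
generate spurious responses; an 8-neighbour kernel is available behind a
flag. The threshold is k × SD where the SD is taken over *all* pixels of
the Laplacian image, including featureless regions. k is validated to
[−10, 0); the default −2.2 is a practical midpoint of the useful −1.5 to
−4 range. A featureless image (SD = 0) yields an empty mask rather than
an all-inclusive one.

Connected components use 8-connectivity by default (diagonal-touching
pixels of one terminal belong together); surviving components are
numbered in raster order of their first pixel, a deterministic
convention chosen for reproducibility. Detection is exactly invariant to
affine intensity rescaling I → aI + b (a > 0), since both ∇²I and its SD
scale by a.

For high-resolution images of broad, flat-topped structures (zero
curvature across the plateau defeats direct Laplacian detection), a
coarse path Gaussian-blurs, block-averages by an integer factor, detects
at low resolution, and block-replicates the label mask back — labels are
never interpolated. In practice the blur/downsample must be strong
enough that the plateau becomes curved at the coarse scale (e.g. a
radius-10 px plateau needs factor ≥ 8, or factor 4 after σ ≈ 3 blur).

## Traces and baseline

Background is the per-frame mean over a user-specified reporter-free
region — always manual, never auto-detected, because only the
experimenter knows where reporter is absent. The ΔF/F baseline is the
centre of the modal histogram bin of each trace, with ⌈1 + log₂N⌉ bins
spanning [min, max] of that trace. The ceiling is used for non-integer
bin counts (more bins localise the mode more finely); modal ties break
toward the lower-valued bin, biasing toward baseline rather than
response plateaus. The estimator overestimates F0 when the activity duty
cycle exceeds ~50% (the mode then sits on the response plateau); the
test suite asserts this direction on a 70%-duty fixture rather than
hiding it. A constant trace is its own baseline (one degenerate bin).
Rows with F0 = 0 cannot be normalised and are set to NaN with a warning
while other rows proceed.

## Clustering

Pairwise trace distances: Pearson (1 − r ∈ [0, 2]), Euclidean,
Manhattan, Chebychev, and "normalised Euclidean", defined here as
Euclidean distance between traces individually standardised to zero mean
and unit variance (population SD); the definition is isolated in one
place so it can be swapped. Constant traces have undefined correlation
and standardisation; they are flagged, their matrix entries set to NaN,
and they are excluded from clustering with a warning.

Flat clustering cuts the single-linkage hierarchy at
cutoff = (fraction/100) × max(d): clusters are connected components of
the graph with edges d < cutoff, using strict inequality (ties at
exactly the cutoff do not link). The equivalence of the component
formulation with a classic single-linkage dendrogram cut is asserted
against an independent hierarchical-clustering oracle on random
instances. Components of size 1 are reported as UNCLUSTERED (label 0) —
a one-member cluster is not a grouping. A degenerate all-zero distance
matrix means all traces are identical and yields a single cluster.
Cluster ids 1…n are assigned in order of each cluster's first member,
for determinism.

## Laminar positions

Borders are open polylines. Resampling places m points uniformly by
cumulative arc length (default m = 8 × image width in pixels, making
vertex spacing ≪ 1 px); smoothing is locally weighted linear regression
(LOWESS, statsmodels, robustness iterations off) of each coordinate
against arc length, default span 0.1 of the contour — the algorithm is
standard, the span is this package's default since no canonical value
exists. Windows covering fewer than 3 points return the input unchanged
with a warning. Orientation matching reverses the second border iff that
reduces the summed endpoint-pair distance, so index-wise pairing does
not cross the layer.

The isocontour family evaluates Cᵢ = (i·C₁₀₀ + (100−i)·C₀)/100 for
i = −1…101 (the −1% and 101% contours are the same formula,
extrapolated, so terminals just outside the borders are binned into the
respective end group); indices 0 and 100 are kept bit-exact copies of
the borders. Centres of mass weight each ROI pixel by the same source
image used for detection. Negative weights (possible in response images)
are clipped to zero with a warning so the centre stays inside the ROI;
zero total mass falls back to the unweighted centroid. Depth is the
index of the isocontour with the smallest vertex-to-point Euclidean
distance; vertex distance (no segment projection) is accurate because of
the dense resampling; ties break toward the lower index.

Polarity calls use three disjoint frame windows: stim_score and
post_score are mean ΔF/F changes relative to the pre-stimulus window in
units of the pre-stimulus sample SD (ddof = 1). ON requires
stim_score ≥ z; OFF requires stim_score ≤ −z or a post-stimulus rebound
without an ON response; otherwise NONRESPONSIVE. The z-gate (default 3)
makes sign-based classification deterministic on noisy traces and is
adjustable in config. Depth histograms use 5%-wide bins spanning −5 to
105 so the extrapolated groups are counted; counts are conserved per
polarity class.

Positions are computed regardless of whether the optical section cuts
the layer orthogonally; that validity judgement is the experimenter's.

## Synthetic data

Generators are bit-reproducible given their seed and return ground truth
in the same encodings the pipeline uses.

Scenes are isotropic Gaussian blobs over a constant or linear-gradient
background with additive Gaussian noise (Poisson shot noise optional,
off by default so analytic checks stay exact). Defaults model the
target regime: a 208×208 field; 20 terminals with peak brightness
uniform on [1, 10] (the ~10-fold expression range); blob σ of
1.5–1.6 px — sub-resolution terminals all appear at roughly the lateral
PSF width, so apparent size is narrowly distributed (~0.75 µm at
0.5 µm/px); noise SD 0.02 of the dimmest peak, the level of a source
image averaged over ~50 frames whose per-frame noise is 0.15 (per-frame
SNR ≈ 7 for the dimmest terminal); centre separation ≥ 12 px. The truth
mask marks pixels within 1σ of each centre. Detection operates on
averaged source images in the real pipeline, so the static-scene default
is the averaged-image noise level; movie generators pass per-frame noise
(0.1–0.2) explicitly.

Movies modulate each blob by phenomenological ΔF/F templates: sustained
step; transient with exponential decay; OFF dip (−0.6 of the amplitude)
with post-stimulus rebound; Poisson-timed spontaneous transients.
Calcium-indicator kinetics are not modelled beyond these shapes. Planted
frame jitter uses wrap-around integer shifts. Layered scenes place
terminals at analytic relative depths between two concentric arcs (a
curved layer, as in a hemispheric retina) or parallel lines, with
rejection sampling keeping terminals in frame and separated.

What passing tests on these fixtures do *not* show about real data:
real terminals are not Gaussian (their steeper edges make Laplacian
ROIs hug them more tightly than the 1σ-disc comparison here), real
movies bleach and drift non-rigidly, neighbouring structures
contaminate traces (no neuropil correction is attempted), and real
response classes are not noiseless templates. The fixtures validate the
machinery, not biological conclusions.

## Numerical choices and degenerate inputs

- SDs of images and traces use population normalisation (ddof 0) except
  the polarity pre-window SD (ddof 1, a small-sample baseline estimate).
- Pearson distances are clipped to [0, 2] to absorb rounding at the
  boundaries; the matrix diagonal is exactly 0.
- Integer registration shifts are applied by exact slicing, not
  interpolation; only subpixel refinement interpolates (linear).
- Empty masks, empty trace matrices, and skipped report stages are legal
  and produce empty-but-valid outputs rather than failures.
- The store is plain CSV; duplicate (experiment_id, roi_id) keys are
  rejected atomically (the store is left untouched).

## Problem sizes

Test fixtures use 208×208 static scenes, 64×64×50 movies for
registration, 128×128 layered scenes, 100-frame traces, and 12-terminal
demo recordings — sizes at which every planted quantity is recoverable
and the whole suite runs in well under a minute, chosen to keep the
feedback loop tight during development.

## Known limitations

- Only rigid-translation registration; no B-spline/affine engines are
  bundled (the estimator hook accepts external ones).
- Single-channel stacks only.
- No bleach correction, neuropil decontamination, or spike inference.
- Wavelet/ICA detection and k-means-style clustering are out of scope;
  morphological closing of masks is deliberately not offered.
- Automatic layer-border detection is not attempted; borders are drawn
  by the experimenter.
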