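# Methods

## Scope and model

`mscstage` implements an image-based pipeline for staging early
adipogenic differentiation of mesenchymal stem cells (MSCs) from
widefield fluorescence fields, together with a chromatin-mobility
analysis of tracked nuclear puncta and a heterochromatin-intensity
quantitation. Because the real image sets are large external downloads,
the package ships a synthetic microscopy generator that reproduces the
statistical structure the analysis assumes; every stage is validated
against that generator's ground truth.

## Synthetic fields

A field is a 16-bit multi-channel image (default 640 x 640 px):

- **Nucleus channel.** Non-overlapping elliptical nuclei (semi-axes
  drawn uniformly from 27-46 px so bounding boxes land in the 50-100 px
  window the size filter keeps). The interior texture is a shot-noise
  field: point impulses smoothed by a Gaussian of width
  `texture_grain_px`, standardized within the nucleus, clipped at +-3
  sd, and mapped onto a fixed intensity band. The autocorrelation of
  such a field at 1 px lag is a function of the grain alone, so the
  gray-level co-occurrence (GLCM) contrast of nucleus interiors is a
  clean, monotone function of grain size.
- **The learnable signal.** Grain size grows geometrically with the
  latent differentiation time, 1.2 px at 0 h to 5 px at 72 h over the
  stage set {0, 6, 24, 48, 72} h. Geometric growth makes interior GLCM
  contrast (roughly proportional to 1/grain^2) log-linearly spaced, so
  each consecutive stage pair is separated by a comparable contrast
  ratio — including the hardest early pair, 0 vs 6 h. This drift is a
  stand-in for whatever nuclear structural factor changes during early
  differentiation; it is a modeling device, not a biological claim.
- **Actin channel.** Oriented line strokes concentrated around nuclei,
  Gaussian-blurred. **Brightfield.** A low-contrast composite of the
  other channels plus noise. Gaussian read noise (sd 150 counts) is
  added to all channels.

Placement rejects overlapping nuclei and fails loudly after 100 retries
per nucleus, naming the density limit. All randomness flows from one
`numpy` generator seeded per call; identical parameters give
bit-identical fields.

What the generator does **not** emulate: optical blur and vignetting,
staining variability between batches, touching/overlapping nuclei,
mitotic figures, debris, and any real biological texture. Passing the
benchmarks therefore shows the pipeline machinery is correct and that
the models can learn a nuclear-texture signal of realistic geometry; it
does not certify accuracy figures on real micrographs.

## Preprocessing and segmentation

16-bit channels are converted to 8-bit by a per-image min-max scaler
(`round(255 (v - min)/(max - min))`, round-half-to-even; constant images
map to zero). The output is invariant to positive affine rescaling of
the input, which is what makes timepoints acquired at different exposure
times comparable. Nuclei are segmented on the DNA-stain channel by Otsu
thresholding over the 256-bin histogram (ties toward the smallest
threshold; verified against an exhaustive between-class-variance scan),
followed by 8-connected component labeling. Regions whose bounding-box
height or width falls outside [50, 100] px are removed; the boundary
values are kept (the removal rule is read with strict inequalities).
"Height" and "width" are axis-aligned bounding-box dimensions. One
global frame size — the elementwise max bbox over all surviving regions
of the whole dataset, not per field — defines fixed-size crops centered
on each region centroid; frames extending past the field are
zero-padded. Border-touching nuclei are flagged and kept by default.
No watershed splitting or hole filling is attempted.

## Augmentation and splits

Each crop is expanded to four copies (0/90/180/270 degrees). Non-square
frames are zero-padded to square first so rotation is a pure pixel
permutation — bit-exact, no interpolation. Train/test divisions are made
at the **field** level (crops from one microscope field are correlated;
splitting them across folds would leak), stratified by timepoint so
every class appears on both sides; the default test fraction is 0.25 and
the default protocol averages over 100 random divisions. Augmented
copies always inherit their source's fold. Field disjointness is
asserted, not assumed, before any metric is computed.

## Staging models

- **Small CNN.** A four-layer network: an input convolution block and
  one hidden convolution block (3 x 3 valid convolutions, 16 and 32
  filters, ReLU, 2 x 2 max pool), flatten, dense output — softmax over
  the 5 stages for classification, a single linear unit for regression.
  Losses: categorical cross-entropy / mean squared error; training is
  25 epochs of mini-batch Adam (lr 1e-3, batch 32), implemented directly
  in NumPy (im2col convolutions, float32 throughout), single-threaded
  and exactly reproducible from the seed. Inputs are resampled to
  32 x 32 per channel and scaled to [0, 1]; regression targets are
  scaled to [0, 1] internally and mapped back to hours. Kernel sizes,
  filter counts, optimizer and batch size are configuration choices, not
  claims about the original network.
- **Multi-channel input** is handled by stacking the requested channels
  (nucleus, actin, nucleus+actin, brightfield) into one tensor.
- **Haralick baseline.** 13 classic Haralick statistics from symmetric,
  normalized GLCMs at distance 1, averaged over the four right-angle
  offsets (making the vector 90-degree-rotation invariant), 256 gray
  levels by default with optional requantization; a random forest (200
  trees) consumes them. Degenerate constant crops get defined values
  (contrast 0, energy 1, correlation 1, entropies 0).
- **Area baseline.** Foreground pixel count after re-thresholding the
  crop by Otsu, fed to the same random forest.
- **Random reference.** Uniform guessing scores 1/k in expectation
  regardless of class counts; an empirical seeded run is reported
  alongside. A shuffled-label control (train-fold labels permuted at the
  source-crop level) estimates the permutation null of the full training
  pipeline.
- **Large-backbone hook.** Any estimator with the same fit/predict
  contract can be slotted in; a flattened-input MLP is wired as the
  default stand-in. Faithful reproduction of a production backbone is
  out of scope.

Test metrics are computed on unaugmented originals; training uses the
4x augmented train fold. Reports carry the split id, confusion matrix,
per-class support, and (for regression) per-crop predictions, MAE and
Pearson r.

## Chromatin mobility

Trajectories are 2D positions in um at uniform frame intervals (default
180 s over 1 h, 21 frames). The chromatin displacement is the
time-averaged squared displacement
`CD(tau) = <(X_{t+tau} - X_t)^2 + (Y_{t+tau} - Y_t)^2>`, lags limited to
half the track duration by default (lags 1-10 of 20) to avoid
high-lag noise. Per-trajectory time averages are combined into an
n_pairs-weighted ensemble mean; both levels are available because the
averaging bracket is ambiguous between time and ensemble. The power law
`CD = D_eff tau^beta` is fitted by OLS in log-log space (the analysis
and its displays live on log-log axes); a nonlinear least-squares
cross-check is provided and agrees within 5% when the log-log fit has
r^2 > 0.99. beta is reported purely as the fitted exponent.

The synthetic trajectory generator draws each axis as fractional
Brownian motion with Hurst exponent beta/2 by Cholesky factorization of
the exact position covariance, each axis carrying half the prefactor, so
`CD(tau) = d_eff tau^beta` holds exactly in expectation at every lag —
an exact oracle for the fitter. Starting positions are spread uniformly
in a 5-um-radius disk (puncta are distributed across the nucleus);
displacements, and hence CD, are unaffected.

Rigid nuclear motion (per-frame rotation + translation, frame 0 =
identity) is estimated against frame 0 by closed-form 2D orthogonal
Procrustes on matched puncta (reflections rejected; >= 3 points
required), or from per-frame masks via centroid drift plus principal-
axis orientation. With static puncta the recovery is exact to machine
precision; with diffusing puncta the rigid fit absorbs ~3/(2n) of the
displacement variance (3 rigid degrees of freedom against 2n point
coordinates), so the registration guarantee — corrected CD within 5% of
the unmoved truth — is validated at n = 40 puncta, a typical telomere
count per nucleus.

Puncta detection is Laplacian-of-Gaussian with scores normalized to
[0, 1] by the frame maximum (a "possibility" surrogate); linking is
greedy nearest-neighbor within a displacement gate, with optional gap
bridging and a minimum track length. Condition comparisons use two-sided
rank-sum tests per parameter (d_eff, beta) with the effect direction;
identical samples report p = 1 with a degenerate flag.

## Intensity quantitation

MFI is the arithmetic mean of raw 16-bit pixel values in a nuclear ROI
(display scaling never enters; means of raw data are what matter).
Optional exposure normalization (`mfi * reference/actual`) is provided
but off by default. ROIs default to the segmentation masks (the original
procedure selected ROIs manually — a stated divergence); external label
masks can be supplied. Group comparisons: Kruskal-Wallis omnibus with
Dunn/Holm post-hoc, or one-way ANOVA with Tukey HSD; significance stars
ns/*/**/***/**** at strict 0.05/0.01/0.001/0.0001 thresholds (p = 0.05
is "ns").

## Numerical and design choices

- Coordinates 0-based row-major; bboxes half-open; all files document
  this.
- 8-bit conversion rounds half-to-even for bit-exactness.
- Otsu ties break toward the smallest threshold.
- The benchmark problem size (5 stages x 20 fields x 10 nuclei ~ 1000
  crops, one 75/25 division for the headline numbers, 500 trajectories
  per power-law cell) keeps the full validation suite comfortably
  desk-scale while leaving binomial noise well below the acceptance
  margins.
- Degenerate inputs are defined, not fatal, wherever a value makes
  sense (constant image in min-max, constant crop in Haralick, identical
  samples in comparisons); they are errors where no value does
  (constant image in Otsu, empty ROI, < 3 usable lags).

## Known limitations

- The CNN is deliberately small and CPU-bound; it is a reference
  implementation of the training protocol, not a performance-tuned
  model.
- Greedy nearest-neighbor linking is not globally optimal and will
  mis-link at high puncta density; the validated regime is well-
  separated puncta at SNR >= 10.
- Mask-based registration assumes elongated nuclei (principal axis
  defined); near-circular masks give unstable rotation estimates —
  point-based registration is preferred when matched puncta exist.
- Real-data accuracy figures are outside what the synthetic benchmark
  can certify.
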