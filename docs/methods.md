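# Methods

## Problem setting

Ki67 is a nuclear proliferation marker visualised by immunohistochemistry
(IHC): proliferating nuclei stain DAB-brown, resting nuclei counterstain
hematoxylin-blue.  The Ki67 index of a patch is operationalised here as the
fraction of *all* patch pixels belonging to positively stained nuclei.
Because Ki67 staining and routine HE staining cannot be done on the same
section, paired adjacent sections are used: the Ki67 section annotates the
HE section cut from the same position.  This package implements, at desk
scale, the full loop around that idea: synthesising annotated HE/Ki67 patch
pairs, recovering the annotation by colour clustering, training a compact
conditional style-based GAN on the labelled HE patches, and evaluating the
generator with FID/FHD/PPL, an interval protocol, Ki67-sweep sequences and
an ordinal rating analysis.

## Synthetic data generator

`synthdata` renders each patch pair from a shared nuclei layout:

* Nuclei are random ellipses (axes 2.5–5.5 % of the patch side, free
  rotation, per-nucleus colour jitter, per-pixel Gaussian noise σ = 2.5).
  Placement is random-sequential with a bounded overlap tolerance that
  grows with the target coverage; a strict hard-core process jams near 55 %
  area coverage, which would decouple high requested indices from realised
  ones, so small overlaps are allowed instead of modelling confluent tissue
  explicitly.
* The HE image paints nuclei hematoxylin-purple on an eosin-pink
  background; the Ki67 image paints the *same* layout blue, with a pixel
  subset of exactly `round(p·H·W)` pixels recoloured DAB-brown (one nucleus
  may be split).  The realised index is therefore exact up to one pixel,
  and `positive_mask ⊆ nuclei_mask` by construction.
* Nuclei coverage is an affine function of the index, `coverage =
  0.12 + 0.88·p`, so coverage ≥ p for every p ≤ 1 and the HE appearance
  carries a recoverable proliferation signal.  Requested indices above the
  achievable packing are clamped with a warning.
* The `paper-imbalanced` label distribution is a Beta(1, 12) body with a
  2.4 % uniform tail on (0.4, 1), giving P(index > 0.5) ≈ 0.020 and a mode
  below 0.1.  Only interval shares of the emulated dataset are published,
  not a parametric form; this mixture is a stand-in chosen to match the
  2 % tail share and the interval ordering.
* Degradation modes for filter testing: Gaussian blur, near-uniform white
  blank, a white tear band of a stated fraction, and nuclei-sparse patches.

What the generator does **not** emulate: tissue morphology (stroma,
necrosis, inflammation), stain physics, registration error between adjacent
sections, or scanner artefacts.  Passing tests therefore demonstrate that
the *pipeline machinery* is correct on data with known ground truth — not
that any component meets clinical performance on real seminoma slides.

## Annotation

`annotate.cluster_stain` k-means-clusters Ki67 patch pixels in RGB (k = 3:
brown / blue / background, seeded, with an exact-assignment fallback when
the image has fewer distinct colours than k).  A cluster is "positive" when
its centroid satisfies the brown rule — HSV hue in [15°, 50°], saturation
> 0.2, value in [0.15, 0.85] — which separates DAB brown from hematoxylin
blue and from background; ties are broken by pixel count.  The index is the
positive-cluster share of all pixels (a tissue-only denominator is
available behind a flag; the all-pixels reading is the default and is what
the synthetic ground truth implements).

The quality filter computes Laplacian variance (blur), Canny edge density,
dark-blob count after Otsu thresholding, tissue fraction (non-near-white
pixels), intensity standard deviation, and the largest near-white connected
component.  Defaults: Laplacian variance ≥ 50, edge density ≥ 0.02, blob
count ≥ 10, tissue fraction ≥ 0.3, intensity std ≥ 4, white-blob fraction
≤ 0.2.  The white-blob criterion is what catches tear artefacts whose
overall tissue fraction is still high.  Thresholds are config-first; the
defaults are calibrated to the synthetic renderer and are not claimed to
match any particular scanner.

`estimate_he_index` recovers an index from an HE patch alone by measuring
the dark-pixel fraction (luminance < 165) and inverting the renderer's
coverage calibration.  It exists because the conditioning and sequence
analyses need an auditable HE-side oracle; it is a synthetic-world proxy
for a learned HE-based Ki67 regressor and is only meaningful for images
drawn from (or trained on) the renderer's palette.

## Conditional generator

The conditioning contract follows the conditional mapping-network design:
the scalar index c passes through a fully connected embedding of
dimensionality `w_dim`, is second-moment normalised exactly like the input
latent z (ε = 1e-8), concatenated with normalised z, and mapped through two
fully connected layers to the intermediate latent w.  Continuous c is
embedded directly (no one-hot).

The synthesis network is deliberately compact: a learned 4×4 constant, three
style-modulated 3×3 convolution blocks (nearest-neighbour upsampling, then a
per-sample channel gain `1 + affine(w)` before each convolution), a final
plain 2× upsample, and a 1×1 convolution to RGB with a sigmoid.  Keeping the
3×3 convolutions at ≤ 32×32 makes single-CPU training practical; alias-free
synthesis machinery is intentionally out of scope.  The discriminator is a
strided conv stack with projection conditioning,
`D(x, c) = ψ(h) + ⟨h, normalise(embed(c))⟩/√d`.

Training uses the non-saturating logistic loss; R1 regularisation
`γ/2 · E‖∇ₓD‖²` with γ = 2 is applied lazily every 8 iterations (weight
scaled by the interval).  The parameter gradient of the penalty is a
Hessian-vector product computed by a central finite difference of the
discriminator's parameter gradient at `x ± εg` — exact to O(ε²) and cheap
relative to automatic double-backward.  Progress is counted in kimgs
(thousands of real images shown).  Evaluation and checkpoints use an
exponential moving average of the generator weights (half-life 10 kimgs),
which stabilises the late-training oscillation a small GAN exhibits.
All networks are implemented in a ~300-line numpy layer library with manual
backpropagation (equalized-learning-rate initialisation, channels-last
im2col convolutions); every layer is covered by finite-difference gradient
checks.

Desk-scale defaults: 64×64 images, z and w dimensionality 64, batch 32,
Adam (lr 1.5e-3, β₁ = 0, β₂ = 0.99), 50 kimgs on 2,000 synthetic pairs —
roughly ten minutes on one CPU core.  These sizes were chosen so the whole
conditioning loop closes convincingly at workstation scale; none of the
published GPU-scale metric values are reproducible in this regime and the
package does not attempt them.

## Metrics

* **FID** — squared Fréchet distance `‖μ_a−μ_b‖² + tr(Σ_a+Σ_b−2(Σ_aΣ_b)^{1/2})`
  between Gaussians fitted (unbiased n−1 covariance) to embedded image
  sets.  The default visual embedder is a fixed-seed two-layer
  random-feature network on 16×16 block-averaged images: deterministic,
  training-free, and sufficient to separate colour/texture populations,
  which is what the desk-scale tests require of an embedding.  The matrix
  square root uses Schur decomposition with a 1e-10 diagonal jitter retry;
  results are clipped at zero.  An independent test oracle computes the
  trace term by diagonalising `Σ_a^{1/2} Σ_b Σ_a^{1/2}`.
* **FHD** — the same distance with the embedding replaced by the
  penultimate layer (64-d) of a small convolutional regressor trained to
  predict the Ki67 index from HE patches (three strided conv layers, global
  average pooling, seeded Adam, MSE).  Which internal layer supplies the
  features is configurable; the penultimate layer is the default.
* **PPL** — mean of `d(G(path(t)), G(path(t+ε)))²/ε²` over latent pairs,
  with spherical interpolation in the input-latent space (linear in the
  intermediate space), ε = 1e-4 by default, and the perceptual distance
  taken in the perceptual random-feature embedding.  The condition is held
  fixed along each path — either a given value or one draw per pair from
  the training label distribution; label handling along conditional paths
  is not otherwise defined, and this is the package's choice.

## Interval protocol

Six half-open intervals (the top interval closed at 1) form the evaluation
hierarchy; relations between intervals (identical / subset / complementary /
overlapping) are derived from bounds, never asserted by hand.  Cross
matrices of FID/FHD between per-interval image sets carry expectation flags
(diagonal, expect-low for nested pairs, expect-high for complementary
pairs).  The violation detector applies two row-wise rules: a diagonal cell
must be its row minimum, and an expect-high cell must not fall below any
expect-low or diagonal cell in its row.  Cells whose interval set has fewer
than two images are reported missing, never imputed — the imbalanced label
distribution can empty the top interval in small runs.  The transcribed
published matrices ship as CSV fixtures, and the detector reproduces the
anomalies called out in the accompanying analysis (the ⟨0.2,0.5) row closer
to its complementary intervals than to its diagonal in the FID matrix; the
diagonal recovered in the FHD matrix).

## Sequences and ratings

A sequence fixes one z and sweeps c over {0, 0.1, …, 0.5} (six images);
grids above 0.5 are allowed but warn, since sweeps beyond 0.5 fell outside
the evaluated range.  The trend statistic is the Spearman rank correlation
between the grid and the annotator-recovered index of each generated image,
defined as 0 with a warning when the recovered indices are constant.  It is
an artifact-level proxy for the experts' "consistent increase" criterion,
not a model of their morphological judgement.

The rating analysis encodes the 5-level verdict scale as ordinals 0–4
(unreal → real) and uses the absolute difference of encoded levels as the
inter-rater distance; this is the unique simple metric under which all the
published summary statistics (70 %/55 % consistency, maxima 2 and 4, the
distance histograms, and every category split) are reproduced exactly from
the transcribed tables.  Weighted-kappa-style coefficients are deliberately
out of scope.

## Numerical and design choices

* float32 throughout the networks; metrics in float64.
* Seeded `numpy.random.Generator` streams everywhere; two runs with the
  same seed produce identical datasets, training trajectories, metric logs
  and generated batches (single-threaded BLAS assumed for bit-identity).
* k-means (scikit-learn, `n_init=4`) is seeded; degenerate images fall back
  to exact distinct-colour assignment with a warning.
* NaN losses abort training with a diagnostic rather than continuing.
* Checkpoints are `.npz` archives holding the EMA generator weights, the
  architecture spec, kimgs reached and the seed.

## Known limitations

* The synthetic textures are far simpler than tissue; all quantitative
  claims are about pipeline correctness, not histopathology.
* The HE-side index estimator inverts the renderer's calibration and does
  not transfer to real HE stains.
* The compact generator trades fidelity for CPU trainability; at 50 kimgs
  it expresses the conditioning signal clearly but images remain coarse.
* Adaptive discriminator augmentation is replaced by optional fixed
  flips/rotations (off by default); its feedback controller is out of
  scope.
* PPL values from the random-feature perceptual embedder are on an
  arbitrary scale; only comparisons within a configuration are meaningful.
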