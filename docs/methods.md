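# Methods

## Data model

A protein chain fragment of N residues is represented by its Cα distance
matrix D ∈ R^{N×N}, d_ij = ‖r_i − r_j‖₂ in Å. Coordinate-derived matrices are
symmetric with zero diagonal and satisfy the triangle inequality; generated
matrices are emitted raw (no symmetrization), so the asymmetry score
‖D − Dᵀ‖_F measures a genuine property of the generator.

Fragments are cut non-overlapping, left to right, from contiguous Cα
segments; trailing residues are discarded. Contiguity policy: a segment ends
where a residue lacks a Cα atom, where residue numbering jumps, or where
consecutive Cα atoms are more than 4.5 Å apart (an intact backbone places
them near 3.8 Å). Alternate locations resolve to the highest occupancy, ties
alphabetically. HETATM records and non-first models are ignored; chains are
fragmented independently. These rules are this package's choices — the
filtering used to build published training sets of this kind is typically
not fully specified.

Model inputs are scaled to [0, 1] by a dataset-wide maximum distance
(clamping above it). The maximum is stored in every dataset container and
checkpoint, so generated outputs are mapped back to Å exactly. A bounded
input is required because the decoder ends in a logistic activation (below).

## Synthetic chains

The built-in generator emulates the statistical regimes of real fragments
without simulating energetics: a self-avoiding walk with

- bond length exactly 3.8 Å (the consecutive-Cα spacing of trans peptides);
- pseudo-bond angle ~ N(105°, 20°), clipped to [45°, 175°], uniform dihedral
  — giving short-range (t ≤ 4) distances around 6–11 Å, as in real chains;
- self-avoidance radius 3.4 Å against all non-consecutive residues, with
  per-step retries and whole-chain restarts (generation error if exhausted).

At n = 32 this yields short-range mean distances ≈ 7.6 Å and long-range
means ≈ 18 Å; at n = 128 contact counts and long-range distances sit in the
regime reported for PDB-derived 128-residue fragments (short-range contacts
of order 300, long-range means of order 20 Å). What the generator does NOT
emulate: secondary-structure regularity, residue identity, the heavy-tailed
compactness distribution of real domains, or experimental noise. Passing
tests on synthetic data therefore demonstrate correctness of the machinery
and qualitative training behavior, not biological fidelity of the model.

## Networks

Reference configuration for 1×128×128 inputs (all shapes asserted by tests):

- **Encoder**: conv(32, 4×4, s2, p1) → conv(64) → [residual 64] → conv(128)
  → [residual 128] → conv(256) — sides 64→32→16→8 — flatten, then two
  parallel fully connected heads give μ and log σ² (latent 512). All
  convolutions carry batch normalization and leaky-ReLU (slope 0.2).
- **Decoder**: fully connected to 256×8×8, then four transposed convolutions
  (4×4, s2, p1) with channels 128→64→32→1 and residual blocks (64, then 32
  filters) after the second and third; the final layer has no normalization
  and a **logistic output**, matching the [0, 1] scaling of distances.
- **Critic**: conv(64, s2, no norm) → conv(128, s2) → conv(256, s4) →
  conv(512, s2), instance normalization on layers 2–4, dropout 0.1 on layers
  1–4, leaky-ReLU throughout; a final valid convolution yields one unbounded
  scalar per item. Ladder sides for a 128 input: 64→32→8→4→1. For smaller
  inputs the final kernel shrinks to the remaining side; inputs below 32 do
  not fit the stride ladder and are rejected at build time.
- **Residual block**: conv(3×3) → norm → activation → conv(3×3) → norm, add
  the skip, then activation. With `use_residual_blocks=False` the blocks are
  omitted entirely (strictly fewer parameters, identical interface) for the
  ablation comparison.

Design choices where the architecture description leaves freedom, fixed here
once: logistic final activation (bounded nonnegative outputs), leaky slope
0.2, weights ~ N(0, 0.02) (seeded), critic consumes the same [0, 1]-scaled
matrices as the VAE. The two latent heads are **zero-initialized** so the
approximate posterior starts exactly at the prior; the KLD then rises from
zero as the encoder learns to use the latent space and stabilizes once
reconstruction and regularization balance — the canonical trajectory for
healthy (non-collapsed) VAE training, and the shape this package's smoke
runs verify.

## Training

Per batch, three phases in order (counters asserted by tests):

1. one encoder+decoder update minimizing `MSE(x, x̂) + β · KLD`,
   KLD = batch mean of −½ Σ_d (1 + log σ² − μ² − σ²);
2. `n_critic = 5` critic updates, each decoding fresh prior noise, minimizing
   `E f(fake) − E f(real) + λ_gp · GP` with λ_gp = 10;
3. one decoder update minimizing `−E f(fake)` on fresh prior noise.

The critic is untouched in phase 1 and the encoder in phases 2–3. Adversarial
phases use pure prior samples (not re-encoded data). Defaults follow the
reference configuration: Adam(1e-4, 0.5, 0.999) for all three networks, 100
epochs, batch 64, checkpoints every 10 epochs. A master seed spawns per-epoch
streams, so runs reproduce bit-for-bit single-threaded.

**KLD weight β.** The reconstruction term here is a pixel MEAN while the KLD
sums over latent dimensions; a unit β would then let the KLD dominate by
three orders of magnitude and collapse the posterior onto the prior. The
default β = 1/N² restores the classical summed-ELBO balance (pixel-sum MSE +
KLD, up to one global factor). Any explicit `kld_weight` overrides this.

**Sampling.** `generate` decodes prior noise in batches and inverts the
scaling to Å. Batch normalization uses batch statistics at sampling time:
running averages of briefly trained models are unrepresentative and produce
degenerate near-constant samples. Outputs are deterministic given seed and
batch size.

## Numerical core

The networks run on `dmgen.nn`, a ~500-line reverse-mode autodiff engine over
float64 NumPy arrays. Convolution and transposed convolution are single
primitives built on im2col/col2im (BLAS matmuls); batch/instance
normalization are composed from differentiable means so their statistics
receive gradients. Engine gradients are verified against central-difference
numerical differentiation in the test suite.

The gradient penalty needs ∂/∂θ of ‖∇_x f(x̃; θ)‖ — a second-order quantity.
The penalty VALUE uses one exact input-gradient backward pass. Its parameter
gradient uses the identity dGP/dθ = Σ_b ∂/∂θ (v_b · ∇_x f(x_b)) with
v_b = (2/B)(‖g_b‖−1) g_b/‖g_b‖ held fixed, and evaluates each directional
derivative by central differences, (f(x+αv) − f(x−αv))/2α with α = 1e-4/max|v|
— two ordinary backward passes. Dropout masks are frozen across the three
critic evaluations so all passes see the same network. Agreement with full
numerical differentiation of the penalty is asserted in the tests (relative
error well under 5% even at artificially amplified curvature; training
behaves identically to exact second-order gradients at these scales).

Instance normalization over a 1×1 spatial field is skipped (affine only):
a single element has no meaningful statistics and normalizing it would erase
the signal (and all input gradients through it).

## Metrics

Sequence separation t = |i − j| classifies residue pairs: t = 1 backbone,
1 < t ≤ 4 short-range, t > 4 long-range. "Within a distance" is closed (≤):
4 Å for the backbone score, 10 Å for short/long-range contacts. Mean
distances average over ALL qualifying pairs of a class, not only contacts.
Features of possibly-asymmetric matrices read the upper triangle (i < j), one
consistent convention, with asymmetry reported separately. Table summaries
use the sample (n−1) standard deviation.

Divergences operate on 1-D per-feature samples: MMD is the square root of the
unbiased squared-MMD estimator with a Gaussian kernel and median-heuristic
bandwidth on the pooled sample (negative estimates clamp to 0; degenerate
pooled samples fall back to bandwidth 1 with a warning); EMD is the 1-D
Wasserstein-1 distance; Bhattacharyya distance uses 50 probability-normalized
bins on the pooled min–max range, capped at −ln(1e-12) for zero overlap. The
kernel, binning and range are recorded in every report since they are
estimator choices, not canonical definitions.

Similarity scores: contact maps binarize at 8 Å over upper-triangle pairs,
excluding the trivially-in-contact t = 1 pairs by default
(`include_backbone=True` restores them); contact score is the Jaccard index
(both-empty maps score 1); dRMSD is the RMS deviation over upper-triangle
entries; the TM-style score applies the classical kernel 1/(1 + (dev/d0)²),
d0(N) = 1.24(N−15)^⅓ − 1.8, to per-pair distance deviations — an adaptation
to distance matrices, labelled as such, not the coordinate-space TM-score.
Set comparisons score each query against every reference and keep, per query,
the best value ("nearest" pairing: max contact/TM, min dRMSD) or the all-pairs
mean; the pairing policy is recorded in the report because aggregated
memorization statistics are not comparable across policies.

## Smoke-study scale

Qualitative training behavior is verified on a scaled-down study chosen once:
256 synthetic 32-residue chains, input side 32, base_filters 8, latent 64,
batch 16, 20 epochs, learning rate 1e-3 (the reference 1e-4 is tuned for
~10⁵ updates on wide networks; the smoke study takes 320 updates on narrow
ones), three seeds in the acceptance script. At this scale the reconstruction
loss ends below half its first-epoch value and the KLD rises from zero and
stabilizes. Asymmetry of generated sets sits far above the untrained
baseline at this scale: an untrained logistic decoder emits nearly constant
(hence nearly symmetric) matrices, while briefly trained generators carry
reconstruction-scale asymmetric error — undercutting the untrained baseline
would require near-converged symmetry learning, i.e. full-scale training.
The corresponding acceptance test asserts the trained<untrained direction
regardless and is expected to fail at desk scale; the acceptance script
reports both values.

## Known limitations

- Fixed fragment length per model; no variable-size inputs.
- CPU-only, float64; the reference 128-residue configuration trains but is
  intended for architecture verification, not full-scale runs.
- The synthetic generator's realism limits (above) bound what desk-scale
  results say about PDB-trained models.
- dRMSD/TM operate on distance matrices directly; no 3-D reconstruction or
  coordinate superposition is performed.
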