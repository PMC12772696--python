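# Methods

`methconvt` classifies disease status from harmonized DNA-methylation
β-value profiles measured across heterogeneous tissues, and attributes the
decision back to individual CpG sites, local co-methylation regions, and
per-subject feature contributions. This note records the model, the
synthetic study conditions, the numerical choices, and the design decisions
that were genuinely open.

## Model

For a subject with β-profile x ∈ [0,1]^P, covariates z ∈ ℝ^K (z-scored age,
binary sex) and tissue code r, the forward pass is:

1. **CpG-wise linear projection.** h_p = w_p·x_p + b_p, one weight and bias
   per site. The map is depthwise (diagonal), never dense: output site p
   depends only on input site p, so after training w reads like a vector of
   per-site regression coefficients and |w| is a global importance score.
   The margin map h is also the quantity penalized by the hinge-margin
   regularizer, tying the interpretable layer directly into the objective.
2. **Convolutional tokenizer.** Two 1-D convolution stages (kernel 9,
   stride 1, zero 'same' padding, GELU), each followed by non-overlapping
   max pooling (8× then 4×), map h to a token sequence T ∈ ℝ^{L×d} with
   L = ⌊⌊P/8⌋/4⌋ ≪ P and d equal to the final channel count. Each token's
   receptive field is a contiguous CpG window with closed-form bounds
   (verified by perturbation tests); fixed sinusoidal positional encodings
   over the token index are added after the encoder. A spec-level guard
   enforces the compression regime L ≤ P/4.
3. **Transformer backbone.** Pre-norm residual blocks with standard scaled
   dot-product multi-head self-attention and a 4d feed-forward expansion;
   dropout after attention and feed-forward during training. The final
   block's per-head L×L attention matrices are retained for
   interpretability. A config flag is reserved for a linear-attention
   variant in earlier blocks; at the scales exercised here standard
   attention is used everywhere, since the distinction only matters at
   much larger L.
4. **Fusion and classifier.** u = mean-pool(tokens) ‖ E_cov(z) ‖ E_tissue[r],
   followed by an affine softmax head. Covariates and tissue enter *only*
   here, so attention maps are pure CpG-token relationships — tested by
   asserting bit-identical attention across tissue codes. The covariate
   embedding is a single affine map to d_cov dimensions; the tissue
   embedding is a learned table row (a fixed effect per region).

Token width d and pooled width D are kept equal (the backbone has constant
width); this is the simplest consistent choice and keeps the parameter
count linear in P (the projection contributes exactly 2P parameters,
asserted against a closed form).

## Objective

The loss on a mini-batch B is

    L = 1/|B| Σ_i [ CE(ỹ_i, ŷ_i) + α · R_margin(y_i±, m_i) ]

* **Label-smoothed cross-entropy.** ỹ places 1−ε+ε/C on the true class and
  ε/C elsewhere (ε=0 recovers one-hot).
* **Top-k hinge-margin regularizer.** With y± = 2y−1 ∈ {−1,+1} and margin
  map m, residuals r_t = max(0, 1 − y±·m_t) are computed per CpG and the
  penalty is the mean of the k largest — supervision concentrates on the
  hardest sites. Ties at the k-th residual are broken toward the lower CpG
  index (the value is unaffected; only the reported hard-site identity is).
  The subgradient is zero outside the current top-k set and at sites with
  margin beyond 1 (checked by finite differences).

Defaults, chosen as conventional magnitudes and all exposed in config:
ε = 0.05, α = 0.1, k = 64, learning rate 1e-3, batch 32, patience 10.
Optimization is Adam with *decoupled* (AdamW-style) weight decay in two
parameter groups — the CpG projection (1e-4) and the rest of the network
(1e-5) — because a per-group "distinct weight decay" is only cleanly
defined in decoupled form. Early stopping monitors validation AUC
(midrank Mann–Whitney on class-1 probabilities) and the best-validation
checkpoint is returned. One master seed fans out (via seed sequences) to
weight initialization, shuffling, and dropout.

The network and optimizer run on a small reverse-mode automatic-
differentiation engine over NumPy written for this package (`autodiff.py`);
every operation's gradient is verified against central finite differences
in the test suite, and gradients of intermediate conv activations — needed
by Grad-CAM++ — are retained on the graph by construction.

Hyperparameter search (`tune`) exposes a declarative search space and a
pluggable engine; the built-in engine is seeded random search, selecting on
validation AUC, and an external Bayesian optimizer can be plugged in
through the same callback interface.

## Attribution stack

* **Linear weights** — read directly off the projection; signed values plus
  |w| as a saliency curve. On planted-signal cohorts the causal sites'
  mean |w|-rank is tested against 10,000 random site sets (permutation p).
* **Grad-CAM++** — for class c with logit y_c, activations A (channel k,
  position t) of a chosen conv stage, and gradients G = ∂y_c/∂A:
  α_{k,t} = G²/(2G² + Σ_u A_u G_u³ + ε̂), channel weights
  w_k = Σ_t α_{k,t}·ReLU(G), map M(t) = ReLU(Σ_k w_k A_{kt}), with
  stabilizer ε̂ = 1e-8. The denominator's cross-position term is implemented
  exactly in this printed form. The map is upsampled to CpG resolution by
  piecewise-linear interpolation over receptive-field centers, constant-
  extended at the sequence ends. Default layer: the last conv stage
  (region-level patterns); `conv0` gives fine-grained maps. Tissue profiles
  average per-sample maps within tissue, and the overall profile averages
  the per-tissue means rather than per-sample maps, so unequal tissue sizes
  do not dominate (per-sample averaging is available; counts are reported).
* **Shapley values** — the normative definition is exact subset enumeration
  with weights |S|!(|F|−|S|−1)!/|F|! and a value function that substitutes
  out-of-coalition features from a single background reference sample,
  holding covariates and tissue fixed. Exact up to |F| = 14 (2^F
  evaluations, batched); beyond that an unbiased permutation-sampling
  estimator with per-feature standard errors. Efficiency, symmetry, and
  dummy axioms are asserted on constructed games, and the sampler is
  checked against exact enumeration within 3 standard errors. Cohort-scale
  curves group contiguous CpGs into windows (default 50 sites) treated as
  single players, each window's φ being assigned to its member sites.
  Default background: the control sample nearest the control centroid
  (configurable to any sample or the control mean).
* **Attention diagnostics** — final-block per-head matrices, their head
  average, and Shannon entropy (natural log) of each averaged row; ln L is
  the uniform-attention ceiling. Entropy is reported per row and as the
  row mean.

## Synthetic cohorts

The generator produces study conditions with known ground truth, emulating
the statistical regime of disease-methylation array data:

* **Bimodal background.** Each CpG is assigned a low (mean β 0.15) or high
  (mean β 0.85) methylation state with equal probability; per-site noise sd
  0.08. This reproduces the familiar bimodal marginal density without
  modeling array chemistry.
* **Co-methylation blocks.** Contiguous blocks (default 20 sites) share a
  latent Gaussian factor: u = √ρ·g_block + √(1−ρ)·e, giving within-block
  Pearson correlation ≈ ρ (default 0.6) on the β scale before clipping.
* **Case effects.** A chosen subset of causal sites receives an additive
  Δβ for cases, directed toward the interior of [0,1] (hypermethylated
  background sites shift down, hypomethylated up), so clipping does not
  erode the planted effect; the empirical case−control gap recovers Δβ
  within Monte-Carlo error.
* **Tissues and covariates.** Per-tissue offsets N(0, 0.03) per site; age
  uniform on [55, 95] with 5% of non-causal sites drifting by 0.02·β per
  standardized year; sex Bernoulli(0.5) with no β effect (sex is a pure
  nuisance covariate). Case fraction 0.5 with exact per-tissue counts.
* **Determinism.** All structure (states, blocks, causal sites) and all
  sample-level draws derive from one seed via separate seed-sequence
  streams; identical config + seed is bit-for-bit reproducible, and
  holdout cohorts reuse the structural stream with a disjoint sample
  stream and id namespace.

What the generator does **not** emulate: probe-type chemistry, detection
p-values, cell-type composition, batch effects beyond per-cohort mean
shifts, or realistic effect-size distributions (real disease effects are
typically far smaller and more diffuse than the planted Δβ used in
recovery tests). Passing the recovery tests therefore demonstrates that
the architecture, objective, and attributions behave correctly on signals
they are designed to detect — not that comparable accuracy is attainable
on real cohorts.

## Study conditions used in tests and the acceptance script

* **Recovery:** P = 2000 CpGs, 50 causal sites at Δβ = 0.25, 600 samples in
  2 tissues, 5 seeds, ≤30 epochs (patience 8). Expected: validation AUC
  ≥ 0.90 for at least 4/5 seeds, and causal-site |w| rank enrichment
  p < 0.01.
* **Null control:** identical pipeline with Δβ = 0 (P = 500 to keep runs
  brisk), 5 seeds, mean test AUC expected in [0.40, 0.60]. Under the null
  a single test split of ~60 samples has a Mann–Whitney sd of ≈0.07, so
  the band is applied to the seed-mean (sd ≈ 0.03), where it is a
  meaningful no-leakage check rather than a coin flip.
* Baselines consume the identical per-seed splits and a flat feature table
  (selected β values, encoded covariates, tissue as one-hot — no learned
  embedding), and are compared with Welch's unequal-variance t-test
  (Welch–Satterthwaite df, two-sided). Baselines are fit on the training
  split only; the deep model additionally uses the validation split for
  early stopping, never for gradient updates.

## Numerical choices and degenerate inputs

* Variance screening uses the unbiased (n−1) estimator on β values, ties
  broken by CpG id ascending; missing entries are mean-imputed within
  tissue (count logged) before variance computation; the selected union is
  ordered lexicographically for a stable feature index.
* Stratified splits use largest-remainder rounding per class (ties toward
  train, then val, then test), guaranteeing class proportions within one
  sample per split.
* Age statistics are computed on the training split and frozen for
  validation/test; a zero sd is an error, as is an unseen tissue code.
* Cross-entropy floors probabilities at 1e-12 (logged when hit); softmax
  and log-softmax are computed in shifted (max-subtracted) form; layer
  norm uses eps 1e-5; attention scales by 1/√d_h.
* Probabilities are validated to sum to 1 within 1e-6; attention rows
  likewise. Non-finite activations abort with the offending block index;
  non-finite losses abort with epoch and batch indices.
* Empty CpG intersections name the two least-overlapping batches;
  duplicate sample ids across cohorts are errors, never silently renamed.

## Known limitations

* The β-scale additive effect model and Gaussian block factor are
  conveniences; they do not model the mean–variance coupling of real
  β values (heteroskedasticity near 0 and 1).
* Exact Shapley is exponential in |F|; cohort-scale curves rely on window
  grouping and short permutation runs, trading variance for tractability.
* The random-search tuner is a baseline engine, not a substitute for a
  sequential model-based optimizer at larger budgets.
* Training is single-process CPU NumPy; the implementation favors
  verifiable gradients over large-scale throughput.
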