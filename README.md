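# methconvt

Interpretable convolution–transformer classification of cross-tissue DNA
methylation profiles.

Epigenome-wide association studies of complex disease routinely find that
single-CpG differential methylation carries little reproducible signal:
volcano plots center on Δβ ≈ 0, few sites survive FDR correction, and
nominal hits rarely replicate across tissues. `methconvt` targets exactly
this regime — many weak, spatially correlated effects distributed across
tissues — by combining a site-level linear layer (for effect-size-style
interpretation) with a convolution–transformer backbone (for local and
long-range co-methylation structure) and explicit covariate/tissue
embeddings, all exercisable end-to-end on synthetic cohorts with known
ground truth.

## Model

For subject i with β-profile x_i ∈ [0,1]^P, covariates z_i (z-scored age,
sex) and tissue code r_i:

    h_i = w ⊙ x_i + b                         (CpG-wise margin map, depthwise)
    T_i = f_conv(h_i) ∈ ℝ^{L×d},  L ≪ P       (1-D conv + pooling tokenizer)
    H_i = f_trans(T_i)                        (pre-norm transformer blocks)
    u_i = Pool(H_i) ‖ E_cov(z_i) ‖ E_tissue(r_i)
    ŷ_i = softmax(W_c u_i + b_c)

trained with label-smoothed cross-entropy plus a top-k hinge-margin
penalty on the margin map,

    L = 1/|B| Σ_i [ CE(ỹ_i, ŷ_i) + α · mean_{t ∈ Top-k} max(0, 1 − y_i^± h_{i,t}) ],

using Adam with decoupled weight decay (separate decay for the projection
layer and the rest) and early stopping on validation AUC. Interpretability
comes at four resolutions: signed per-CpG projection weights, Grad-CAM++
saliency over conv feature maps upsampled through receptive-field centers,
exact/sampled Shapley attributions with background substitution, and
final-block attention maps with row entropies. See `docs/methods.md` for
the full account.

The network runs on a small reverse-mode autodiff engine over NumPy
(`methconvt/autodiff.py`) whose gradients are finite-difference-verified
in the test suite.

## Worked example

```python
import numpy as np
from methconvt import PipelineConfig, SyntheticConfig, run_single_seed, generate_cohort
from methconvt.interpret import linear_importance
from scipy import stats

cfg = PipelineConfig(
    synthetic=SyntheticConfig(
        n_samples_per_tissue=300, n_tissues=2, n_cpgs=2000,
        n_causal=50, effect_size=0.25, seed=7,
    ),
    train=dict(max_epochs=30, patience=8),
)
row = run_single_seed(cfg, seed=1)
print(f"test AUC {row['auc']:.3f}  ACC {row['acc']:.3f}  F1 {row['f1']:.3f}  "
      f"(best val AUC {row['best_val_auc']:.3f} at epoch {row['best_epoch']})")

_, _, truth = generate_cohort(cfg.synthetic)
_, curve = linear_importance(row["model"])
ranks = stats.rankdata(-curve.values)
print(f"mean |w|-rank of the 50 causal sites: {ranks[truth.causal_indices].mean():.1f} "
      f"of {cfg.synthetic.n_cpgs} (chance: {(cfg.synthetic.n_cpgs + 1) / 2:.1f})")
```

prints

```
test AUC 1.000  ACC 1.000  F1 1.000  (best val AUC 1.000 at epoch 2)
mean |w|-rank of the 50 causal sites: 656.7 of 2000 (chance: 1000.5)
```

The cohort plants 50 causal CpGs with a case–control gap of Δβ = 0.25 in a
2000-site, two-tissue cohort of 600 samples; the model separates cases
cleanly on the held-out test split, and the trained projection weights
rank the planted sites well above the chance rank of ~1000 (early stopping
halts training long before the weights fully concentrate — a permutation
test puts the enrichment at p < 1e-4).

The same flow is available from the shell:

```bash
methconvt simulate --out data/ --seed 7
methconvt preprocess --beta data/beta.tsv --samples data/samples.csv --k 5000 --out prep/
methconvt train --data data/ --seed 1 --out run/
methconvt explain --model run/checkpoint.npz --data data/ --out explained/
methconvt benchmark --seeds 5 --out bench/
```

Every output directory carries the resolved config and seed
(`run_config.yaml`, `run_manifest.json`); rerunning from a stored config
reproduces metrics bit-for-bit.

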