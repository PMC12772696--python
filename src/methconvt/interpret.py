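"""Multi-resolution attribution: per-CpG linear weights, Grad-CAM++ over the
convolutional feature maps, Shapley values with background substitution, and
final-block attention maps with row entropies.

The three saliency sources answer different questions at different scales:

* **Linear weights** — the depthwise projection's coefficients, readable like
  regression coefficients: a global, signed, per-site effect.
* **Grad-CAM++** — position-specific α weights turn class-logit gradients on
  a conv feature map into a non-negative activation map over token positions;
  upsampling through the encoder's receptive-field centers yields a
  region-level saliency curve over all P sites.
* **Shapley values** — a per-subject cooperative-game attribution: each
  CpG feature's average marginal contribution to the class probability over
  coalitions, with out-of-coalition features substituted from a background
  reference sample and covariates/tissue held fixed.  Exact enumeration for
  small feature sets, an unbiased permutation-sampling estimator otherwise.

* **Attention** — the final transformer block's per-head L × L matrices,
  their head average, and the Shannon entropy (natural log) of each averaged
  row; low entropy means concentrated token dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

from . import autodiff as ad
from .model import MethConvTransformer

EXACT_SHAPLEY_LIMIT = 14


@dataclass
class SaliencyCurve:
    values: np.ndarray  # length P, non-negative
    source: str  # {linear, gradcampp, shap_mean}
    class_index: int


@dataclass
class ShapleyAttribution:
    phi: np.ndarray  # one value per explained feature
    class_index: int
    background_id: str | None
    explained_features: np.ndarray
    standard_error: np.ndarray | None = None


@dataclass
class AttentionBundle:
    per_head: np.ndarray  # (H, L, L)
    averaged: np.ndarray  # (L, L)
    row_entropies: np.ndarray  # (L,)

    @property
    def mean_entropy(self) -> float:
        return float(self.row_entropies.mean())


# ---------------------------------------------------------------------------
# linear projection importance
# ---------------------------------------------------------------------------

def linear_importance(model: MethConvTransformer, class_index: int = 1):
    """Signed projection weights and their magnitudes as a saliency curve."""
    signed = model.params["proj_w"].data.copy()
    curve = SaliencyCurve(np.abs(signed), source="linear", class_index=class_index)
    return signed, curve


# ---------------------------------------------------------------------------
# Grad-CAM++
# ---------------------------------------------------------------------------

def gradcam_core(activations: np.ndarray, gradients: np.ndarray,
                 eps: float = 1e-8) -> np.ndarray:
    """Position-wise Grad-CAM++ map from a (C, L') feature map and the class
    logit's gradients of the same shape.

    alpha[k,t] = G[k,t]^2 / (2 G[k,t]^2 + sum_u A[k,u] G[k,u]^3 + eps)
    w[k]       = sum_t alpha[k,t] * relu(G[k,t])
    M[t]       = relu(sum_k w[k] * A[k,t])
    """
    a = np.asarray(activations, float)
    g = np.asarray(gradients, float)
    if a.shape != g.shape:
        raise ValueError("activations and gradients must share shape")
    g2 = g**2
    denom = 2.0 * g2 + (a * g**3).sum(axis=1, keepdims=True) + eps
    alpha = g2 / denom
    w = (alpha * np.maximum(g, 0.0)).sum(axis=1)
    return np.maximum((w[:, None] * a).sum(axis=0), 0.0)


def _upsample(map_values: np.ndarray, fields: np.ndarray, p: int) -> np.ndarray:
    """Piecewise-linear interpolation over receptive-field centers, clipped
    (constant-extended) at the sequence ends."""
    centers = fields.mean(axis=1)
    return np.interp(np.arange(p), centers, map_values)


def _resolve_stage(model: MethConvTransformer, layer_choice: str) -> int:
    n = len(model.spec.conv_channels)
    names = {f"conv{s}": s for s in range(n)}
    names["first"] = 0
    names["last"] = n - 1
    if layer_choice not in names:
        raise ValueError(f"unknown layer {layer_choice!r}; choose from {sorted(names)}")
    return names[layer_choice]


def gradcam_pp(model: MethConvTransformer, x, z, r, class_index: int = 1,
               layer_choice: str = "last", eps: float = 1e-8) -> SaliencyCurve:
    """Grad-CAM++ saliency for one sample, upsampled to CpG resolution."""
    if class_index >= model.spec.n_classes:
        raise ValueError("class_index out of range")
    stage = _resolve_stage(model, layer_choice)
    res = model.forward(np.atleast_2d(x), np.atleast_2d(z), np.atleast_1d(r))
    onehot = np.zeros_like(res.logits.data)
    onehot[:, class_index] = 1.0
    ad.backward(res.logits, grad=onehot)
    act = res.conv_activations[stage]
    cam = gradcam_core(act.data[0], act.grad[0], eps=eps)
    fields = model.spec.receptive_fields(stage)
    values = _upsample(cam, fields, model.spec.P)
    return SaliencyCurve(values, source="gradcampp", class_index=class_index)


def gradcam_tissue_profile(model: MethConvTransformer, x, z, r,
                           class_index: int = 1, layer_choice: str = "last"):
    """Per-tissue mean Grad-CAM++ curves and their across-tissue mean.

    The overall profile averages the per-tissue means (not per-sample maps),
    so tissues with many samples do not dominate; per-tissue sample counts
    are reported alongside.
    """
    x = np.atleast_2d(x)
    z = np.atleast_2d(z)
    r = np.atleast_1d(np.asarray(r, int))
    per_tissue: dict[int, SaliencyCurve] = {}
    counts: dict[int, int] = {}
    for t in sorted(set(r.tolist())):
        idx = np.where(r == t)[0]
        maps = [
            gradcam_pp(model, x[i], z[i], [t], class_index, layer_choice).values
            for i in idx
        ]
        per_tissue[t] = SaliencyCurve(
            np.mean(maps, axis=0), source="gradcampp", class_index=class_index
        )
        counts[t] = len(idx)
    overall = SaliencyCurve(
        np.mean([c.values for c in per_tissue.values()], axis=0),
        source="gradcampp",
        class_index=class_index,
    )
    return per_tissue, overall, counts


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

def model_value_fn(model: MethConvTransformer, z, r, class_index: int = 1):
    """Class-`class_index` probability as a function of the β vector alone,
    with covariates and tissue fixed (the value function's wrapper)."""
    z = np.atleast_2d(np.asarray(z, float))
    r = np.atleast_1d(np.asarray(r, int))

    def predict(mat: np.ndarray) -> np.ndarray:
        mat = np.atleast_2d(mat)
        n = mat.shape[0]
        return model.predict_proba(
            mat, np.repeat(z, n, axis=0), np.repeat(r, n, axis=0)
        )[:, class_index]

    return predict


def shapley_exact(predict_fn, x, background, features=None,
                  class_index: int = 1,
                  background_id: str | None = None) -> ShapleyAttribution:
    """Exact Shapley values by subset enumeration (|F| <= 14).

    phi_j = sum over S ⊆ F\\{j} of |S|!(|F|-|S|-1)!/|F|! * [v(S∪{j}) - v(S)],
    where v substitutes features outside the coalition with the background's
    values.  Satisfies efficiency: sum phi = f(x) - f(background).
    """
    x = np.asarray(x, float)
    features = (
        np.arange(x.size) if features is None else np.asarray(features, int)
    )
    f = features.size
    if f > EXACT_SHAPLEY_LIMIT:
        raise ValueError(
            f"|F|={f} too large for exact enumeration; use shapley_sampled"
        )
    n_masks = 1 << f
    in_coalition = np.array(
        [[bool(m >> j & 1) for j in range(f)] for m in range(n_masks)]
    )
    rows = np.repeat(x[None, :], n_masks, axis=0)
    for j in range(f):
        out = ~in_coalition[:, j]
        rows[out, features[j]] = background[features[j]]
    values = np.asarray(predict_fn(rows), float)

    weights = np.array(
        [factorial(s) * factorial(f - s - 1) / factorial(f) for s in range(f)]
    )
    phi = np.zeros(f)
    sizes = in_coalition.sum(axis=1)
    for j in range(f):
        without_j = np.where(~in_coalition[:, j])[0]
        with_j = without_j | (1 << j)
        phi[j] = (weights[sizes[without_j]] * (values[with_j] - values[without_j])).sum()
    return ShapleyAttribution(
        phi=phi, class_index=class_index, background_id=background_id,
        explained_features=features,
    )


def shapley_sampled(predict_fn, x, background, features=None,
                    class_index: int = 1, n_permutations: int = 200,
                    seed: int = 0, background_id: str | None = None,
                    chunk: int = 4096) -> ShapleyAttribution:
    """Monte-Carlo permutation estimate of the Shapley values.

    Unbiased; converges to the exact enumeration as permutations grow.
    Per-feature standard errors from the spread of marginal contributions.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, float)
    features = (
        np.arange(x.size) if features is None else np.asarray(features, int)
    )
    f = features.size
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(f) for _ in range(n_permutations)])

    # build all prefix configurations: row (perm p, step s) has the first s
    # features of permutation p at their true values, the rest background
    rows = np.repeat(np.atleast_2d(background), n_permutations * (f + 1), axis=0)
    rows[:, :] = background[None, :]
    # non-explained coordinates stay at x's own values (held fixed)
    fixed = np.setdiff1d(np.arange(x.size), features)
    rows[:, fixed] = x[fixed]
    for p in range(n_permutations):
        base = p * (f + 1)
        for s in range(1, f + 1):
            idx = features[perms[p, : s]]
            rows[base + s, idx] = x[idx]
    values = np.empty(rows.shape[0])
    for start in range(0, rows.shape[0], chunk):
        values[start : start + chunk] = predict_fn(rows[start : start + chunk])

    contrib = np.zeros((n_permutations, f))
    for p in range(n_permutations):
        base = p * (f + 1)
        deltas = np.diff(values[base : base + f + 1])
        contrib[p, perms[p]] = deltas
    phi = contrib.mean(axis=0)
    se = (
        contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
        if n_permutations > 1
        else np.full(f, np.nan)
    )
    return ShapleyAttribution(
        phi=phi, class_index=class_index, background_id=background_id,
        explained_features=features, standard_error=se,
    )


def control_centroid_background(beta_values: np.ndarray,
                                diagnosis: np.ndarray,
                                sample_ids: list[str] | None = None):
    """Default background policy: the control sample closest (L2) to the
    control-group centroid."""
    controls = np.where(np.asarray(diagnosis, int) == 0)[0]
    if controls.size == 0:
        raise ValueError("no control samples available for background")
    centroid = beta_values[controls].mean(axis=0)
    best = controls[np.argmin(((beta_values[controls] - centroid) ** 2).sum(axis=1))]
    bid = sample_ids[best] if sample_ids is not None else str(best)
    return beta_values[best].copy(), bid


def shap_cohort_profile(model: MethConvTransformer, x, z, r,
                        background: np.ndarray, class_index: int = 1,
                        window_size: int = 50, n_permutations: int = 8,
                        seed: int = 0, background_id: str | None = None):
    """Cohort-mean Shapley curve over all P CpGs plus the per-sample matrix.

    For tractability contiguous CpGs are grouped into windows of
    ``window_size`` sites; each window is one player and its φ is assigned
    to every member site, so curves stay on the full CpG index.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 0:
        raise ValueError("empty cohort")
    z = np.atleast_2d(z)
    r = np.atleast_1d(np.asarray(r, int))
    p = model.spec.P
    starts = np.arange(0, p, window_size)
    per_sample = np.zeros((x.shape[0], p))
    for i in range(x.shape[0]):
        predict = model_value_fn(model, z[i], r[i], class_index)
        phi_w = _windowed_shapley(
            predict, x[i], background, starts, window_size, p,
            n_permutations, seed + i,
        )
        for w, s in enumerate(starts):
            per_sample[i, s : s + window_size] = phi_w[w]
    mean_curve = SaliencyCurve(
        np.abs(per_sample.mean(axis=0)), source="shap_mean", class_index=class_index
    )
    return mean_curve, per_sample


def _windowed_shapley(predict_fn, x, background, starts, width, p,
                      n_permutations, seed) -> np.ndarray:
    """Permutation Shapley over contiguous windows treated as single players."""
    f = starts.size
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(f) for _ in range(n_permutations)])
    rows = np.repeat(np.atleast_2d(background), n_permutations * (f + 1), axis=0)
    for q in range(n_permutations):
        base = q * (f + 1)
        for s in range(1, f + 1):
            row = rows[base + s]
            row[:] = background
            for w in perms[q, : s]:
                lo = starts[w]
                row[lo : lo + width] = x[lo : lo + width]
    values = predict_fn(rows)
    contrib = np.zeros((n_permutations, f))
    for q in range(n_permutations):
        base = q * (f + 1)
        contrib[q, perms[q]] = np.diff(values[base : base + f + 1])
    return contrib.mean(axis=0)


# ---------------------------------------------------------------------------
# attention diagnostics
# ---------------------------------------------------------------------------

def row_entropy(matrix: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of each row; 0·log 0 := 0."""
    m = np.asarray(matrix, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log(m), 0.0)
    return -terms.sum(axis=-1)


def attention_analysis(model: MethConvTransformer, x, z, r) -> AttentionBundle:
    """Final-block attention for one sample: per-head maps, head average,
    and per-row entropies of the averaged map."""
    res = model.forward(np.atleast_2d(x), np.atleast_2d(z), np.atleast_1d(r))
    per_head = res.attention.data[0]  # (H, L, L)
    averaged = per_head.mean(axis=0)
    return AttentionBundle(
        per_head=per_head, averaged=averaged, row_entropies=row_entropy(averaged)
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def attribution_table(cpg_ids: list[str], signed_linear: np.ndarray,
                      gradcampp: np.ndarray | None = None,
                      mean_shap: np.ndarray | None = None):
    """Attribution bundle as a tidy DataFrame on a shared CpG index."""
    import pandas as pd

    data = {
        "cpg_id": cpg_ids,
        "signed_linear_weight": signed_linear,
        "abs_linear_weight": np.abs(signed_linear),
    }
    if gradcampp is not None:
        data["gradcampp"] = gradcampp
    if mean_shap is not None:
        data["mean_shap"] = mean_shap
    return pd.DataFrame(data)
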