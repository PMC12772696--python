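"""MethConvTransformer: CpG-wise projection, convolutional tokenizer,
transformer backbone, covariate/tissue fusion, and softmax classifier.

Architecture, in order:

1. **CpG-wise linear projection** — a depthwise (diagonal) map
   ``h[p] = w[p] * x[p] + b[p]``: one weight per CpG, no cross-site mixing,
   so the trained weights read like per-site regression coefficients and the
   margin map ``h`` doubles as the input to the hinge-margin regularizer.
2. **Convolutional encoder** — stacked 1-D convolutions (stride 1, 'same'
   padding, GELU) each followed by non-overlapping max pooling, compressing
   the P-length margin map into L ≪ P tokens of width d.  Every token's
   receptive field is a contiguous, computable CpG window, which Grad-CAM++
   uses to upsample saliency back to site resolution.  Fixed sinusoidal
   positional encodings over the token index are added after the encoder.
3. **Transformer backbone** — pre-norm residual blocks with standard scaled
   dot-product self-attention; the final block's per-head attention matrices
   are retained for interpretability.
4. **Fusion head** — mean-pooled tokens ‖ covariate embedding ‖ tissue
   embedding, followed by an affine softmax classifier.  Tissue and
   covariates enter only here, so attention maps are pure CpG-token
   relationships.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class ModelSpec:
    P: int
    conv_channels: tuple[int, ...] = (8, 16)
    conv_kernel: int = 9
    pool_sizes: tuple[int, ...] = (8, 4)
    n_layers: int = 2
    n_heads: int = 4
    d_cov: int = 8
    d_r: int = 4
    n_tissues: int = 2
    n_classes: int = 2
    n_covariates: int = 2
    dropout: float = 0.1
    full_attention_last_block: bool = True

    def __post_init__(self):
        if self.conv_kernel % 2 == 0 or self.conv_kernel < 1:
            raise ValueError("conv_kernel must be odd and positive")
        if len(self.conv_channels) != len(self.pool_sizes):
            raise ValueError("conv_channels and pool_sizes must have equal length")
        if self.P < self.conv_kernel:
            raise ValueError("P must be at least conv_kernel")
        if self.d % self.n_heads:
            raise ValueError("token width d must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.L > self.P // 4:
            raise ValueError(f"token count L={self.L} violates L <= P/4")
        if self.L < 1:
            raise ValueError("pooling consumes the whole sequence")

    @property
    def d(self) -> int:
        """Token width; equal to the last conv stage's channel count (the
        backbone keeps a constant width, so pooled width D = d)."""
        return self.conv_channels[-1]

    @property
    def L(self) -> int:
        length = self.P
        for p in self.pool_sizes:
            length //= p
        return length

    def stage_lengths(self) -> list[int]:
        lengths, length = [], self.P
        for p in self.pool_sizes:
            length //= p
            lengths.append(length)
        return lengths

    def receptive_fields(self, stage: int | None = None) -> np.ndarray:
        """Input-CpG windows [start, end] (inclusive) of each position of a
        conv stage's pooled feature map (default: last stage = tokens)."""
        n_stages = len(self.conv_channels)
        stage = n_stages - 1 if stage is None else stage
        a, lo, hi = 1, 0, 0  # pos j covers input [a*j + lo, a*j + hi]
        half = self.conv_kernel // 2
        length = self.P
        for s in range(stage + 1):
            lo -= a * half
            hi += a * half
            p = self.pool_sizes[s]
            hi += a * (p - 1)
            a *= p
            length //= p
        pos = np.arange(length)
        bounds = np.stack([a * pos + lo, a * pos + hi], axis=1)
        return np.clip(bounds, 0, self.P - 1)


def sinusoidal_encoding(length: int, width: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(width)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / width)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


@dataclass
class ForwardResult:
    logits: Tensor
    margins: Tensor
    attention: Tensor | None  # final block, (B, H, L, L)
    conv_activations: list[Tensor] = field(default_factory=list)

    @property
    def probabilities(self) -> np.ndarray:
        return ad.softmax(self.logits, axis=-1).data


class MethConvTransformer:
    """The classifier; parameters are autodiff Tensors keyed by name."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        p = {}
        # near-identity projection: training reshapes it into per-site effects
        p["proj_w"] = Tensor(1.0 + 0.01 * rng.normal(size=spec.P))
        p["proj_b"] = Tensor(np.zeros(spec.P))
        c_in = 1
        for s, c_out in enumerate(spec.conv_channels):
            scale = np.sqrt(2.0 / (c_in * spec.conv_kernel))
            p[f"conv{s}_w"] = Tensor(rng.normal(0, scale, (c_out, c_in, spec.conv_kernel)))
            p[f"conv{s}_b"] = Tensor(np.zeros(c_out))
            c_in = c_out
        d = spec.d
        glorot = lambda fan_in, fan_out: rng.normal(
            0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out)
        )
        for l in range(spec.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"block{l}_{name}"] = Tensor(glorot(d, d))
            p[f"block{l}_bo"] = Tensor(np.zeros(d))
            p[f"block{l}_ln1_g"] = Tensor(np.ones(d))
            p[f"block{l}_ln1_b"] = Tensor(np.zeros(d))
            p[f"block{l}_ln2_g"] = Tensor(np.ones(d))
            p[f"block{l}_ln2_b"] = Tensor(np.zeros(d))
            p[f"block{l}_ffn_w1"] = Tensor(glorot(d, 4 * d))
            p[f"block{l}_ffn_b1"] = Tensor(np.zeros(4 * d))
            p[f"block{l}_ffn_w2"] = Tensor(glorot(4 * d, d))
            p[f"block{l}_ffn_b2"] = Tensor(np.zeros(d))
        p["ln_f_g"] = Tensor(np.ones(d))
        p["ln_f_b"] = Tensor(np.zeros(d))
        p["cov_w"] = Tensor(glorot(spec.n_covariates, spec.d_cov))
        p["cov_b"] = Tensor(np.zeros(spec.d_cov))
        p["tissue_emb"] = Tensor(0.01 * rng.normal(size=(spec.n_tissues, spec.d_r)))
        fused = d + spec.d_cov + spec.d_r
        p["head_w"] = Tensor(glorot(fused, spec.n_classes))
        p["head_b"] = Tensor(np.zeros(spec.n_classes))
        self.params: dict[str, Tensor] = p
        self.pos_encoding = sinusoidal_encoding(spec.L, d)

    # ------------------------------------------------------------------
    def projection_param_names(self) -> list[str]:
        return ["proj_w", "proj_b"]

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    # ------------------------------------------------------------------
    def cpg_project(self, x) -> Tensor:
        """Per-CpG margin map h[p] = w[p]·x[p] + b[p] (no cross-site mixing)."""
        x = ad.as_tensor(x)
        if x.shape[-1] != self.spec.P:
            raise ValueError(
                f"input has {x.shape[-1]} CpGs, model expects {self.spec.P}"
            )
        return x * self.params["proj_w"] + self.params["proj_b"]

    def conv_encode(
        self, h: Tensor, collect: list[Tensor] | None = None
    ) -> Tensor:
        """Margin map (B, P) -> token sequence (B, L, d) with positional
        encodings added; post-pool activations of each stage are appended to
        `collect` for Grad-CAM++."""
        b = h.shape[0]
        cur = h.reshape(b, 1, self.spec.P)
        for s in range(len(self.spec.conv_channels)):
            cur = ad.conv1d_same(
                cur, self.params[f"conv{s}_w"], self.params[f"conv{s}_b"]
            ).gelu()
            cur = ad.maxpool1d(cur, self.spec.pool_sizes[s])
            if collect is not None:
                collect.append(cur)
        tokens = cur.transpose(0, 2, 1)  # (B, L, d)
        return tokens + Tensor(self.pos_encoding)

    def _attention_block(self, tokens: Tensor, layer: int, train, rng):
        spec = self.spec
        b, length, d = tokens.shape
        h, dh = spec.n_heads, d // spec.n_heads
        pre = ad.layer_norm(
            tokens, self.params[f"block{layer}_ln1_g"], self.params[f"block{layer}_ln1_b"]
        )
        def heads(w):
            return (pre @ self.params[f"block{layer}_{w}"]).reshape(
                b, length, h, dh
            ).transpose(0, 2, 1, 3)
        q, k, v = heads("wq"), heads("wk"), heads("wv")
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)  # (B, H, L, L)
        mixed = attn
        if train and spec.dropout:
            mixed = ad.dropout(mixed, spec.dropout, rng)
        ctx = (mixed @ v).transpose(0, 2, 1, 3).reshape(b, length, d)
        out = ctx @ self.params[f"block{layer}_wo"] + self.params[f"block{layer}_bo"]
        if train and spec.dropout:
            out = ad.dropout(out, spec.dropout, rng)
        return tokens + out, attn

    def _ffn_block(self, tokens: Tensor, layer: int, train, rng):
        pre = ad.layer_norm(
            tokens, self.params[f"block{layer}_ln2_g"], self.params[f"block{layer}_ln2_b"]
        )
        hidden = (pre @ self.params[f"block{layer}_ffn_w1"] + self.params[f"block{layer}_ffn_b1"]).gelu()
        out = hidden @ self.params[f"block{layer}_ffn_w2"] + self.params[f"block{layer}_ffn_b2"]
        if train and self.spec.dropout:
            out = ad.dropout(out, self.spec.dropout, rng)
        return tokens + out

    def transformer_forward(
        self, tokens: Tensor, train: bool = False, rng=None
    ) -> tuple[Tensor, Tensor | None]:
        """Run the backbone; returns (final tokens, last-block attention)."""
        attention = None
        for l in range(self.spec.n_layers):
            tokens, attn = self._attention_block(tokens, l, train, rng)
            tokens = self._ffn_block(tokens, l, train, rng)
            if l == self.spec.n_layers - 1:
                attention = attn
            if not np.all(np.isfinite(tokens.data)):
                raise FloatingPointError(f"non-finite activations in block {l}")
        tokens = ad.layer_norm(tokens, self.params["ln_f_g"], self.params["ln_f_b"])
        return tokens, attention

    def fuse(self, tokens: Tensor, z, r) -> Tensor:
        """Mean-pool tokens and concatenate covariate and tissue embeddings
        (the only place tissue/covariate information enters the network)."""
        r = np.asarray(r, int)
        if r.min() < 0 or r.max() >= self.spec.n_tissues:
            raise ValueError(
                f"tissue code out of range [0, {self.spec.n_tissues})"
            )
        pooled = tokens.mean(axis=1)
        cov = ad.as_tensor(z) @ self.params["cov_w"] + self.params["cov_b"]
        tis = ad.take_rows(self.params["tissue_emb"], r)
        return ad.concat([pooled, cov, tis], axis=1)

    def classify(self, fused: Tensor) -> Tensor:
        """Fused representation -> class probabilities."""
        return ad.softmax(self.logits(fused), axis=-1)

    def logits(self, fused: Tensor) -> Tensor:
        return fused @ self.params["head_w"] + self.params["head_b"]

    def forward(self, x, z, r, train: bool = False, rng=None) -> ForwardResult:
        """Full forward pass on a batch: x (B, P) β-values, z (B, K)
        covariates, r (B,) tissue codes.  Deterministic when train=False."""
        x = np.atleast_2d(np.asarray(x, float))
        z = np.atleast_2d(np.asarray(z, float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input β values")
        margins = self.cpg_project(x)
        conv_acts: list[Tensor] = []
        tokens = self.conv_encode(margins, collect=conv_acts)
        tokens, attention = self.transformer_forward(tokens, train=train, rng=rng)
        fused = self.fuse(tokens, z, r)
        logits = self.logits(fused)
        return ForwardResult(
            logits=logits,
            margins=margins,
            attention=attention,
            conv_activations=conv_acts,
        )

    def predict_proba(self, x, z, r, batch_size: int = 256) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        z = np.atleast_2d(np.asarray(z, float))
        r = np.atleast_1d(np.asarray(r, int))
        out = []
        for start in range(0, x.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out.append(self.forward(x[sl], z[sl], r[sl]).probabilities)
        return np.vstack(out)

    # -- persistence ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(state[k], float).copy()

    def save(self, path, cpg_ids: list[str] | None = None) -> None:
        meta = {"schema_version": "1", "spec": asdict(self.spec)}
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        if cpg_ids is not None:
            arrays["cpg_ids"] = np.array(cpg_ids)
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> tuple["MethConvTransformer", list[str] | None]:
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            spec_dict = meta["spec"]
            spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
            spec_dict["pool_sizes"] = tuple(spec_dict["pool_sizes"])
            model = cls(ModelSpec(**spec_dict))
            model.load_state_dict(
                {k[len("param::"):]: npz[k] for k in npz.files if k.startswith("param::")}
            )
            cpgs = npz["cpg_ids"].tolist() if "cpg_ids" in npz.files else None
        return model, cpgs
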