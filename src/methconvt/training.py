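"""Training objective and loop.

The loss is a batch mean of label-smoothed cross-entropy plus a CpG-wise
hinge-margin regularizer::

    L = 1/|B| * sum_i [ CE(y_tilde_i, y_hat_i) + alpha * R_margin(y_pm_i, m_i) ]

where the smoothed target puts 1 - eps + eps/C on the true class and eps/C
elsewhere, and R_margin is the mean of the top-k largest hinge residuals
max(0, 1 - y_pm * m_t) over the per-CpG margin map m — supervision is
concentrated on the hardest sites rather than diluted over all P.

Optimization is Adam with decoupled (AdamW-style) weight decay applied
per parameter group: the CpG projection layer gets its own decay, the rest
of the network another.  Early stopping monitors validation AUC and the
best-validation checkpoint is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .evaluation import roc_auc
from .model import MethConvTransformer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossConfig:
    epsilon: float = 0.05  # label smoothing
    alpha: float = 0.1  # margin-regularizer weight
    top_k: int = 64
    n_classes: int = 2

    def __post_init__(self):
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay_projection: float = 1e-4
    weight_decay_rest: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.weight_decay_projection < 0 or self.weight_decay_rest < 0:
            raise ValueError("weight decay must be >= 0")


# ---------------------------------------------------------------------------
# loss pieces (NumPy-level reference forms used directly in tests/reports)
# ---------------------------------------------------------------------------

def smooth_labels(y: int | np.ndarray, n_classes: int, epsilon: float) -> np.ndarray:
    """Smoothed target: 1 - eps + eps/C at the true class, eps/C elsewhere."""
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    y = np.atleast_1d(np.asarray(y, int))
    if (y < 0).any() or (y >= n_classes).any():
        raise ValueError("class index out of range")
    target = np.full((y.size, n_classes), epsilon / n_classes)
    target[np.arange(y.size), y] = 1.0 - epsilon + epsilon / n_classes
    return target if target.shape[0] > 1 else target[0]


def cross_entropy(smoothed: np.ndarray, probs: np.ndarray) -> float:
    """-sum_c y_tilde_c log y_hat_c, with probabilities floored at 1e-12."""
    probs = np.asarray(probs, float)
    if np.any((probs <= 0) & (np.asarray(smoothed) > 0)):
        logger.warning("zero probability at a target class; clamping at 1e-12")
    return float(-(np.asarray(smoothed) * np.log(np.maximum(probs, 1e-12))).sum())


def margin_regularizer(y_pm: int, m: np.ndarray, top_k: int) -> float:
    """Mean of the top-k largest hinge residuals max(0, 1 - y_pm * m_t)."""
    m = np.asarray(m, float)
    if y_pm not in (-1, 1):
        raise ValueError("y_pm must be -1 or +1")
    if not 1 <= top_k <= m.size:
        raise ValueError("top_k must be in [1, P]")
    residuals = np.maximum(0.0, 1.0 - y_pm * m)
    # ties at the k-th residual: lower CpG index wins (stable sort on -r)
    order = np.argsort(-residuals, kind="stable")
    return float(residuals[order[:top_k]].mean())


def total_loss(y: np.ndarray, probs: np.ndarray, margins: np.ndarray,
               cfg: LossConfig) -> float:
    """Batch-mean CE + alpha * margin terms (reference implementation)."""
    y = np.atleast_1d(np.asarray(y, int))
    if y.size == 0:
        raise ValueError("empty batch")
    probs = np.atleast_2d(probs)
    margins = np.atleast_2d(margins)
    per_sample = []
    for i, yi in enumerate(y):
        ce = cross_entropy(smooth_labels(yi, cfg.n_classes, cfg.epsilon), probs[i])
        reg = margin_regularizer(int(2 * yi - 1), margins[i], cfg.top_k)
        per_sample.append(ce + cfg.alpha * reg)
    return float(np.mean(per_sample))


# ---------------------------------------------------------------------------
# differentiable loss graph used by the optimizer
# ---------------------------------------------------------------------------

def _loss_graph(logits: Tensor, margins: Tensor, y: np.ndarray,
                cfg: LossConfig) -> Tensor:
    targets = np.atleast_2d(smooth_labels(y, cfg.n_classes, cfg.epsilon))
    log_probs = ad.log_softmax(logits, axis=-1)
    ce = -(Tensor(targets) * log_probs).sum(axis=-1)
    if cfg.alpha == 0.0:
        return ce.mean()
    y_pm = (2 * np.asarray(y, int) - 1).astype(float)[:, None]
    residuals = (1.0 - Tensor(y_pm) * margins).relu()
    order = np.argsort(-residuals.data, axis=-1, kind="stable")[:, : cfg.top_k]
    top = ad.gather_last(residuals, order)
    return (ce + cfg.alpha * top.mean(axis=-1)).mean()


class AdamW:
    """Adam with decoupled weight decay, one decay per parameter group."""

    def __init__(self, groups: list[tuple[dict[str, Tensor], float, float]],
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {
            name: (np.zeros_like(t.data), np.zeros_like(t.data))
            for params, _, _ in groups
            for name, t in params.items()
        }
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for params, lr, wd in self.groups:
            for name, tensor in params.items():
                g = tensor.grad
                if g is None:
                    continue
                m, v = self.state[name]
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                m_hat = m / (1 - b1**self.t)
                v_hat = v / (1 - b2**self.t)
                tensor.data -= lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                     + wd * tensor.data)


@dataclass
class TrainResult:
    model: MethConvTransformer
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def train(
    model: MethConvTransformer,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    train_cfg: TrainConfig,
    loss_cfg: LossConfig,
) -> TrainResult:
    """Fit the model; each data tuple is (x, z, r, y).

    One master seed fans out to shuffling and dropout streams.  Training
    stops once validation AUC has not improved for `patience` epochs; the
    checkpoint with the best validation AUC is restored before returning.
    """
    x_tr, z_tr, r_tr, y_tr = train_data
    x_va, z_va, r_va, y_va = val_data
    ss = np.random.SeedSequence([train_cfg.seed, 101])
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    proj_names = set(model.projection_param_names())
    proj = {k: v for k, v in model.params.items() if k in proj_names}
    rest = {k: v for k, v in model.params.items() if k not in proj_names}
    opt = AdamW(
        [
            (proj, train_cfg.learning_rate, train_cfg.weight_decay_projection),
            (rest, train_cfg.learning_rate, train_cfg.weight_decay_rest),
        ]
    )

    n = x_tr.shape[0]
    best_auc, best_state, best_epoch, stale = -np.inf, None, -1, 0
    history: list[dict] = []
    for epoch in range(train_cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            res = model.forward(
                x_tr[idx], z_tr[idx], r_tr[idx], train=True, rng=dropout_rng
            )
            loss = _loss_graph(res.logits, res.margins, y_tr[idx], loss_cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // train_cfg.batch_size}"
                )
            ad.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        val_scores = model.predict_proba(x_va, z_va, r_va)[:, 1]
        val_auc = roc_auc(y_va, val_scores)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
        )
        if val_auc > best_auc:
            best_auc, best_state, best_epoch, stale = val_auc, model.state_dict(), epoch, 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(
        model=model, history=history, best_epoch=best_epoch, best_val_auc=best_auc
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _sample_params(search_space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, decl in search_space.items():
        kind = decl["type"]
        if kind == "float":
            out[name] = float(rng.uniform(decl["low"], decl["high"]))
        elif kind == "log_float":
            out[name] = float(
                np.exp(rng.uniform(np.log(decl["low"]), np.log(decl["high"])))
            )
        elif kind == "int":
            out[name] = int(rng.integers(decl["low"], decl["high"] + 1))
        elif kind == "categorical":
            out[name] = decl["choices"][rng.integers(len(decl["choices"]))]
        else:
            raise ValueError(f"unknown search-space type {kind!r} for {name!r}")
    return out


def tune(objective, search_space: dict, budget: int, seed: int = 0,
         engine=None) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Maximize validation AUC over a declared search space.

    `objective(params) -> AUC`.  The optimization engine is pluggable: pass a
    callable `engine(objective, search_space, budget, seed)` to delegate to an
    external Bayesian optimizer; the built-in default is seeded random search.
    Returns (best params, best AUC, all completed trials).
    """
    if not search_space:
        raise ValueError("empty search space")
    if engine is not None:
        return engine(objective, search_space, budget, seed)
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []
    for _ in range(budget):
        params = _sample_params(search_space, rng)
        try:
            score = float(objective(params))
        except Exception as exc:  # noqa: BLE001 - record and move on
            logger.warning("trial %r failed: %s", params, exc)
            continue
        trials.append((params, score))
    if not trials:
        raise RuntimeError("all tuning trials failed")
    best_params, best_score = max(trials, key=lambda t: t[1])
    return best_params, best_score, trials
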