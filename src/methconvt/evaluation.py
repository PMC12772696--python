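"""Metrics, the multi-seed repetition protocol, and the baseline comparison
harness with Welch's unequal-variance t-test.

AUC uses the rank (Mann-Whitney) formulation with midranks for ties, so it
is exactly the probability that a random case outscores a random control
(ties counting one half).  Accuracy and F1 (positive class = case) are
computed at a fixed 0.5 threshold on the class-1 probability.  Experiments
are repeated over seeds, with the seed driving split assignment, weight
initialization and shuffling, and models are compared per metric with
Welch's two-sample t-test.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data import BetaMatrix, SampleTable
from .model import MethConvTransformer, ModelSpec
from .preprocessing import encode_covariates, select_variable_cpgs, stratified_split
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    y = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: y_true contains a single class")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class Metrics:
    auc: float | None
    acc: float
    f1: float


def compute_metrics(y_true, scores, threshold: float = 0.5) -> Metrics:
    """AUC / accuracy / F1 from class-1 probabilities.

    With single-class labels AUC is undefined and reported as None; accuracy
    and F1 are still returned.
    """
    y = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    pred = (s >= threshold).astype(int)
    acc = float((pred == y).mean())
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    try:
        auc = roc_auc(y, s)
    except ValueError:
        logger.warning("AUC undefined (single-class labels); returning None")
        auc = None
    return Metrics(auc=auc, acc=acc, f1=float(f1))


def welch_test(a, b) -> tuple[float, float]:
    """Welch's two-sample t (unequal variances, Welch-Satterthwaite df),
    two-sided p.  Degenerate zero-variance samples with equal means give
    t = 0, p = 1."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# pipeline: one full split/train/test cycle per seed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run split -> train -> test on one cohort."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    loss: dict = field(default_factory=dict)  # LossConfig overrides
    feature_k: int | None = None  # per-tissue variance screen, None = all CpGs
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)


def _split_arrays(beta: BetaMatrix, table: SampleTable, split, age_stats=None):
    """Materialize (x, z, r, y) arrays per split with train-frozen age stats."""
    out = {}
    for name in ("train", "val", "test"):
        ids = split.ids(name)
        sub = table.subset(ids)
        if name == "train":
            z, r, age_stats = encode_covariates(sub, age_stats)
        else:
            z, r, _ = encode_covariates(sub, age_stats)
        out[name] = (
            beta.subset_samples(ids).values,
            z,
            r,
            sub.diagnosis,
        )
    return out, age_stats


def split_hash(split) -> str:
    text = ";".join(f"{s}:{g}" for s, g in sorted(split.assignment.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_single_seed(cfg: PipelineConfig, seed: int,
                    cohort=None) -> dict:
    """Split, train and evaluate once; returns metrics plus artifacts.

    The cohort itself is fixed by ``cfg.synthetic.seed``; `seed` drives the
    split, initialization and shuffling (pass ``cohort=(beta, table)`` to
    reuse generated data across seeds).
    """
    from .training import LossConfig, TrainConfig, train  # local: cycle

    if cohort is None:
        beta, table, _ = generate_cohort(cfg.synthetic)
    else:
        beta, table = cohort
    if cfg.feature_k is not None:
        sel = select_variable_cpgs(beta, table, cfg.feature_k)
        beta = beta.subset_cpgs(sel.selected_ids)
    split = stratified_split(table, cfg.fractions, seed=seed)
    arrays, age_stats = _split_arrays(beta, table, split)

    spec = ModelSpec(
        P=beta.n_cpgs,
        n_tissues=int(table.tissue.max()) + 1,
        **cfg.model,
    )
    model = MethConvTransformer(spec, seed=seed)
    result = train(
        model,
        arrays["train"],
        arrays["val"],
        TrainConfig(seed=seed, **cfg.train),
        LossConfig(**cfg.loss),
    )
    x_te, z_te, r_te, y_te = arrays["test"]
    scores = model.predict_proba(x_te, z_te, r_te)[:, 1]
    metrics = compute_metrics(y_te, scores)
    return {
        "seed": seed,
        "auc": metrics.auc,
        "acc": metrics.acc,
        "f1": metrics.f1,
        "best_val_auc": result.best_val_auc,
        "best_epoch": result.best_epoch,
        "n_epochs": len(result.history),
        "split_hash": split_hash(split),
        "model": model,
        "history": result.history,
        "test_scores": scores,
        "arrays": arrays,
        "age_stats": age_stats,
        "cpg_ids": beta.cpg_ids,
    }


@dataclass
class MetricsReport:
    per_seed: list[dict]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed)


def aggregate(per_seed: list[dict], metrics=("auc", "acc", "f1")) -> MetricsReport:
    report = MetricsReport(per_seed=per_seed)
    for m in metrics:
        vals = np.array([row[m] for row in per_seed], float)
        report.mean[m] = float(vals.mean())
        # sd only defined for n >= 2 (n-1 denominator)
        report.sd[m] = float(vals.std(ddof=1)) if len(vals) >= 2 else None
    return report


def multiseed_run(cfg: PipelineConfig, seeds: list[int],
                  keep_models: bool = False) -> MetricsReport:
    """Repeat the full split/train/test cycle per seed and aggregate.

    Per-seed failures are recorded and the run continues.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    beta, table, _ = generate_cohort(cfg.synthetic)
    rows, failures = [], []
    for seed in seeds:
        try:
            row = run_single_seed(cfg, seed, cohort=(beta, table))
        except Exception as exc:  # noqa: BLE001 - protocol records failures
            logger.warning("seed %d failed: %s", seed, exc)
            failures.append((seed, str(exc)))
            continue
        if not keep_models:
            row = {k: v for k, v in row.items()
                   if k not in ("model", "arrays", "test_scores")}
        rows.append(row)
    report = aggregate(rows)
    report.failures = failures
    return report


# ---------------------------------------------------------------------------
# baseline benchmark
# ---------------------------------------------------------------------------

def baseline_registry(seed: int = 0) -> dict:
    """Standard tabular classifiers; every model sees the identical
    selected-CpG + covariate (+ tissue one-hot) feature table."""
    return {
        "gaussian_nb": lambda: GaussianNB(),
        "logistic_regression_l1": lambda: LogisticRegression(
            penalty="l1", solver="liblinear", max_iter=2000, random_state=seed
        ),
        "logistic_regression_l2": lambda: LogisticRegression(
            max_iter=2000, random_state=seed
        ),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "linear_svm": lambda: SVC(
            kernel="linear", probability=True, random_state=seed
        ),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=500, random_state=seed
        ),
    }


def _tabular_features(x, z, r, n_tissues: int) -> np.ndarray:
    onehot = np.eye(n_tissues)[np.asarray(r, int)]
    return np.hstack([x, z, onehot])


@dataclass(frozen=True)
class ComparisonRow:
    model_name: str
    metric_name: str
    mean: float
    sd: float
    t_statistic: float | None  # None for the reference model itself
    p_value: float | None


def benchmark(cfg: PipelineConfig, baseline_names: list[str],
              seeds: list[int]) -> list[ComparisonRow]:
    """Compare the conv-transformer against baseline classifiers on identical
    per-seed splits and feature tables; Welch's t per metric."""
    registry = baseline_registry()
    unknown = [b for b in baseline_names if b not in registry]
    if unknown:
        raise ValueError(
            f"unknown baselines {unknown}; available: {sorted(registry)}"
        )
    beta, table, _ = generate_cohort(cfg.synthetic)
    n_tissues = int(table.tissue.max()) + 1
    per_model: dict[str, list[dict]] = {"methconvtransformer": []}
    for name in baseline_names:
        per_model[name] = []

    for seed in seeds:
        row = run_single_seed(cfg, seed, cohort=(beta, table))
        per_model["methconvtransformer"].append(row)
        arrays = row["arrays"]
        x_tr, z_tr, r_tr, y_tr = arrays["train"]
        x_te, z_te, r_te, y_te = arrays["test"]
        f_tr = _tabular_features(x_tr, z_tr, r_tr, n_tissues)
        f_te = _tabular_features(x_te, z_te, r_te, n_tissues)
        for name in baseline_names:
            clf = baseline_registry(seed)[name]()
            clf.fit(f_tr, y_tr)
            scores = clf.predict_proba(f_te)[:, 1]
            m = compute_metrics(y_te, scores)
            per_model[name].append(
                {"seed": seed, "auc": m.auc, "acc": m.acc, "f1": m.f1,
                 "split_hash": row["split_hash"]}
            )
    # identical splits across models within a seed, verified by hash
    for name in baseline_names:
        for ref_row, base_row in zip(per_model["methconvtransformer"], per_model[name]):
            assert ref_row["split_hash"] == base_row["split_hash"]

    rows: list[ComparisonRow] = []
    for metric in ("auc", "acc", "f1"):
        ref = np.array([r[metric] for r in per_model["methconvtransformer"]], float)
        rows.append(
            ComparisonRow(
                "methconvtransformer", metric,
                float(ref.mean()),
                float(ref.std(ddof=1)) if len(ref) > 1 else float("nan"),
                None, None,
            )
        )
        for name in baseline_names:
            vals = np.array([r[metric] for r in per_model[name]], float)
            if len(seeds) >= 2:
                t, p = welch_test(vals, ref)
            else:
                t, p = None, None
            rows.append(
                ComparisonRow(
                    name, metric, float(vals.mean()),
                    float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    t, p,
                )
            )
    return rows


def comparison_table(rows: list[ComparisonRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model": r.model_name,
                "metric": r.metric_name,
                "mean": r.mean,
                "sd": r.sd,
                "t": r.t_statistic,
                "p": r.p_value,
            }
            for r in rows
        ]
    )
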