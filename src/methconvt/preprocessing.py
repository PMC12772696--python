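"""Cohort merging, per-tissue variance feature selection, covariate encoding,
and stratified train/val/test splitting.

The feature screen mirrors EWAS practice: for every tissue the top-k CpGs by
within-tissue sample variance (unbiased, n−1 denominator) are kept and the
modeling feature set is their union, ordered lexicographically so feature
indices — and therefore positional encodings — are stable across runs.
Age statistics are estimated on the training split only and frozen for reuse
on validation/test to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BetaMatrix, SampleTable

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class FeatureSelection:
    selected_ids: list[str]
    per_tissue_topk: dict[int, list[str]]
    k: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.selected_ids) + "\n")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # sample_id -> train/val/test
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.assignment), "split": list(self.assignment.values())}
        )


def intersect_and_merge(
    matrices: list[BetaMatrix], tables: list[SampleTable]
) -> tuple[BetaMatrix, SampleTable]:
    """Align cohorts on the intersection of their CpG sets and stack samples.

    The output CpG set is the intersection of all input sets in lexicographic
    order; rows are the concatenation of all samples with the cohort column
    recording origin.
    """
    if not matrices:
        raise ValueError("need at least one BetaMatrix")
    if len(matrices) != len(tables):
        raise ValueError("matrices and tables must pair up")
    sets = [set(m.cpg_ids) for m in matrices]
    common = set.intersection(*sets)
    if not common:
        worst, size = None, None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                ov = len(sets[i] & sets[j])
                if size is None or ov < size:
                    worst, size = (i, j), ov
        raise ValueError(
            "empty CpG intersection across batches; smallest pairwise overlap "
            f"is between batch {worst[0]} and batch {worst[1]} ({size} probes)"
        )
    order = sorted(common)
    aligned = [m.subset_cpgs(order) for m in matrices]
    all_ids = [s for m in aligned for s in m.sample_ids]
    if len(set(all_ids)) != len(all_ids):
        dupes = sorted({s for s in all_ids if all_ids.count(s) > 1})
        raise ValueError(f"duplicate sample_id across cohorts: {dupes[:5]}")
    values = np.vstack([m.values for m in aligned])
    merged_table = SampleTable(
        pd.concat([t.aligned_to(m).df for m, t in zip(matrices, tables)],
                  ignore_index=True)
    )
    return BetaMatrix(values, order, all_ids), merged_table.aligned_to(
        BetaMatrix(values, order, all_ids)
    )


def select_variable_cpgs(
    beta: BetaMatrix, samples: SampleTable, k: int
) -> FeatureSelection:
    """Top-k most variable CpGs within each tissue; union across tissues.

    Variance uses the unbiased (n−1) estimator; ties are broken by CpG id
    ascending; missing entries are mean-imputed within tissue (logged).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    samples = samples.aligned_to(beta)
    tissues = samples.tissue
    ids = np.array(beta.cpg_ids)
    per_tissue: dict[int, list[str]] = {}
    for t in sorted(set(tissues.tolist())):
        rows = beta.values[tissues == t]
        if rows.shape[0] < 2:
            raise ValueError(f"tissue {t} has fewer than 2 samples")
        missing = ~np.isfinite(rows)
        if missing.any():
            logger.info("tissue %d: mean-imputing %d missing entries", t, missing.sum())
            col_mean = np.nanmean(np.where(missing, np.nan, rows), axis=0)
            rows = np.where(missing, col_mean[None, :], rows)
        var = rows.var(axis=0, ddof=1)
        # sort by (-variance, cpg_id): lexsort keys are applied last-key-major
        order = np.lexsort((ids, -var))
        per_tissue[t] = ids[order[: min(k, len(ids))]].tolist()
    union = sorted(set().union(*per_tissue.values()))
    return FeatureSelection(selected_ids=union, per_tissue_topk=per_tissue, k=k)


def encode_covariates(
    samples: SampleTable, age_stats: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Encode (z-scored age, binary sex) covariates; tissue codes returned
    separately because they feed the embedding, not the covariate vector.

    When ``age_stats`` is None the mean/sd (ddof=1) are estimated from the
    given samples and returned for reuse on validation/test data.
    """
    age = samples.age
    if not np.all(np.isfinite(age)):
        raise ValueError("non-finite ages")
    if age_stats is None:
        mean, sd = float(age.mean()), float(age.std(ddof=1))
    else:
        mean, sd = map(float, age_stats)
    if sd <= 0:
        raise ValueError("age sd must be positive")
    cov = np.column_stack([(age - mean) / sd, samples.sex.astype(float)])
    return cov, samples.tissue.copy(), (mean, sd)


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    remainder = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def stratified_split(
    samples: SampleTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Class-stratified train/val/test partition.

    Per-class counts come from largest-remainder rounding of the fractions
    (ties broken in train, val, test order), so every split's class
    proportion matches the global proportion to within one sample per class.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    y = samples.diagnosis
    ids = np.array(samples.sample_ids)
    assignment: dict[str, str] = {}
    for cls in sorted(set(y.tolist())):
        members = ids[y == cls]
        if len(members) < 3:
            raise ValueError(f"class {cls} has fewer than 3 samples")
        members = members[rng.permutation(len(members))]
        counts = _largest_remainder(len(members), fractions)
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            for s in members[start : start + c]:
                assignment[str(s)] = name
            start += c
    # restore original sample order for readability
    assignment = {s: assignment[s] for s in samples.sample_ids}
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)
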