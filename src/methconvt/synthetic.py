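"""Synthetic multi-tissue methylation cohorts with known ground truth.

The generator emulates the statistical regime of disease-methylation array
studies rather than array chemistry: each CpG sits in a "low" (mean β ≈ 0.15)
or "high" (mean β ≈ 0.85) methylation state, giving the familiar bimodal
marginal density; contiguous blocks of CpGs share a latent Gaussian factor so
co-methylation is tunable; a chosen subset of causal sites receives an
additive Δβ case effect (directed toward the interior of [0,1] so clipping
does not erode the planted effect); tissues differ by small per-site offsets;
and a subset of sites drifts with standardized age.  Everything is driven by
a single seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BetaMatrix, SampleTable

LOW_MEAN = 0.15
HIGH_MEAN = 0.85
NOISE_SD = 0.08
TISSUE_OFFSET_SD = 0.03
AGE_SITE_FRACTION = 0.05
AGE_LOW, AGE_HIGH = 55.0, 95.0
_AGE_MEAN = 0.5 * (AGE_LOW + AGE_HIGH)
_AGE_SD = (AGE_HIGH - AGE_LOW) / np.sqrt(12.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_samples_per_tissue: int = 300
    n_tissues: int = 2
    n_cpgs: int = 2000
    n_causal: int = 50
    effect_size: float = 0.15  # case-minus-control Δβ at causal sites
    block_size: int = 20
    block_corr: float = 0.6
    age_effect: float = 0.02  # Δβ per standardized year at age-drift sites
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_samples_per_tissue", self.n_samples_per_tissue >= 1),
            ("n_tissues", self.n_tissues >= 1),
            ("n_cpgs", self.n_cpgs >= 1),
            ("n_causal", 0 <= self.n_causal <= self.n_cpgs),
            ("effect_size", 0.0 <= self.effect_size <= 1.0),
            ("block_size", 1 <= self.block_size <= self.n_cpgs),
            ("block_corr", 0.0 <= self.block_corr < 1.0),
            ("case_fraction", 0.0 < self.case_fraction < 1.0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SyntheticConfig field: {name}")


@dataclass
class GroundTruth:
    causal_indices: np.ndarray  # sorted CpG indices carrying the case effect
    causal_directions: np.ndarray  # ±1 per causal site
    per_tissue_offsets: np.ndarray  # (n_tissues, n_cpgs)
    block_assignments: np.ndarray  # (n_cpgs,) block id per CpG
    age_site_indices: np.ndarray = field(default_factory=lambda: np.array([], int))


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{p:08d}" for p in range(n)]


def _structure(config: SyntheticConfig):
    """Cohort-level structure shared by the main and holdout draws."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    p = config.n_cpgs
    blocks = np.arange(p) // config.block_size
    state_high = rng.random(p) < 0.5
    base_mean = np.where(state_high, HIGH_MEAN, LOW_MEAN)
    offsets = rng.normal(0.0, TISSUE_OFFSET_SD, size=(config.n_tissues, p))
    causal = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    directions = np.where(state_high[causal], -1.0, 1.0)
    non_causal = np.setdiff1d(np.arange(p), causal)
    n_age = min(int(round(AGE_SITE_FRACTION * p)), non_causal.size)
    age_sites = np.sort(rng.choice(non_causal, size=n_age, replace=False))
    truth = GroundTruth(
        causal_indices=causal,
        causal_directions=directions,
        per_tissue_offsets=offsets,
        block_assignments=blocks,
        age_site_indices=age_sites,
    )
    return base_mean, truth


def _draw_samples(
    config: SyntheticConfig,
    base_mean: np.ndarray,
    truth: GroundTruth,
    rng: np.random.Generator,
    id_prefix: str,
    cohort: str,
):
    p = config.n_cpgs
    n_per = config.n_samples_per_tissue
    n_total = n_per * config.n_tissues
    n_blocks = int(truth.block_assignments.max()) + 1
    rho = config.block_corr

    diagnosis = np.zeros(n_total, int)
    tissue = np.zeros(n_total, int)
    n_cases = int(round(config.case_fraction * n_per))
    if n_cases == 0 or n_cases == n_per:
        raise ValueError("invalid SyntheticConfig field: case_fraction")
    for t in range(config.n_tissues):
        sl = slice(t * n_per, (t + 1) * n_per)
        tissue[sl] = t
        diagnosis[t * n_per : t * n_per + n_cases] = 1

    age = rng.uniform(AGE_LOW, AGE_HIGH, size=n_total)
    sex = (rng.random(n_total) < 0.5).astype(int)

    factors = rng.normal(size=(n_total, n_blocks))
    noise = rng.normal(size=(n_total, p))
    latent = np.sqrt(rho) * factors[:, truth.block_assignments] + np.sqrt(1 - rho) * noise

    beta = base_mean[None, :] + truth.per_tissue_offsets[tissue] + NOISE_SD * latent
    if config.n_causal:
        effect = config.effect_size * truth.causal_directions
        beta[:, truth.causal_indices] += diagnosis[:, None] * effect[None, :]
    if truth.age_site_indices.size:
        z_age = (age - _AGE_MEAN) / _AGE_SD
        beta[:, truth.age_site_indices] += config.age_effect * z_age[:, None]
    np.clip(beta, 0.0, 1.0, out=beta)

    sample_ids = [f"{id_prefix}{i:05d}" for i in range(n_total)]
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "diagnosis": diagnosis,
                "age": age,
                "sex": sex,
                "tissue": tissue,
                "cohort": cohort,
            }
        )
    )
    return BetaMatrix(beta, _cpg_ids(p), sample_ids), table


def generate_cohort(config: SyntheticConfig):
    """Generate the main cohort.

    Returns (BetaMatrix, SampleTable, GroundTruth); identical config + seed
    reproduces identical output bit-for-bit.
    """
    base_mean, truth = _structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    beta, table = _draw_samples(config, base_mean, truth, rng, "S", "synthetic_main")
    return beta, table, truth


def holdout_cohort(config: SyntheticConfig, seed: int):
    """Draw new samples from the same generative process (same CpG universe,
    same planted structure, disjoint random stream and sample-id namespace)."""
    base_mean, truth = _structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, seed]))
    beta, table = _draw_samples(
        config, base_mean, truth, rng, f"H{seed}_", "synthetic_holdout"
    )
    return beta, table
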