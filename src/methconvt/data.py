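"""Core data containers: β-value matrices and sample sheets.

A :class:`BetaMatrix` is a samples × CpG matrix of methylation fractions in
[0, 1]; a :class:`SampleTable` carries per-sample phenotype and covariates
(diagnosis 0/1, age in years, sex 0/1, integer tissue code, cohort string).
Both round-trip through plain delimited text so cohorts from different
sources can be merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "diagnosis", "age", "sex", "tissue", "cohort"]


@dataclass
class BetaMatrix:
    values: np.ndarray  # (n_samples, P), float
    cpg_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        n, p = self.values.shape
        if len(self.cpg_ids) != p:
            raise ValueError(f"cpg_ids length {len(self.cpg_ids)} != {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"sample_ids length {len(self.sample_ids)} != {n} rows")
        if len(set(self.cpg_ids)) != p:
            raise ValueError("duplicated cpg_ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample_ids")
        finite = np.isfinite(self.values)
        if finite.any() and (
            self.values[finite].min() < 0 or self.values[finite].max() > 1
        ):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of explicitly-flagged (NaN) entries."""
        return ~np.isfinite(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.columns), [str(s) for s in df.index])

    def subset_samples(self, ids: list[str]) -> "BetaMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[s] for s in ids]
        return BetaMatrix(self.values[rows], self.cpg_ids, list(ids))

    def subset_cpgs(self, ids: list[str]) -> "BetaMatrix":
        pos = {c: j for j, c in enumerate(self.cpg_ids)}
        cols = [pos[c] for c in ids]
        return BetaMatrix(self.values[:, cols], list(ids), self.sample_ids)


@dataclass
class SampleTable:
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        self.df = self.df[SAMPLE_COLUMNS].reset_index(drop=True)
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id in sample table")
        if not set(self.df["diagnosis"].unique()) <= {0, 1}:
            raise ValueError("diagnosis must be coded 0 (control) / 1 (case)")
        if not set(self.df["sex"].unique()) <= {0, 1}:
            raise ValueError("sex must be coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def diagnosis(self) -> np.ndarray:
        return self.df["diagnosis"].to_numpy(int)

    @property
    def age(self) -> np.ndarray:
        return self.df["age"].to_numpy(float)

    @property
    def sex(self) -> np.ndarray:
        return self.df["sex"].to_numpy(int)

    @property
    def tissue(self) -> np.ndarray:
        return self.df["tissue"].to_numpy(int)

    def __len__(self) -> int:
        return len(self.df)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def subset(self, ids: list[str]) -> "SampleTable":
        sub = self.df.set_index("sample_id").loc[ids].reset_index()
        return SampleTable(sub)

    def aligned_to(self, beta: BetaMatrix) -> "SampleTable":
        """Reorder rows to match a BetaMatrix; every sample must be present."""
        have = set(self.df["sample_id"])
        want = beta.sample_ids
        absent = [s for s in want if s not in have]
        if absent:
            raise ValueError(f"samples missing from table: {absent[:5]}")
        return self.subset(want)
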