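"""In-memory containers shared across the pipeline.

Genotypes live in a :class:`GenotypeMatrix`: an individuals x markers
matrix of biallelic allele dosages (0/1/2) stored as floats with NaN
marking missing calls.  Phenotypes are long-format pandas DataFrames with
one row per plot record (individual, harvest, block, value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ("individual", "harvest", "block", "value")


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with missingness as NaN."""

    dosages: np.ndarray
    individuals: np.ndarray = field(default=None)
    markers: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers array")
        n, m = self.dosages.shape
        if self.individuals is None:
            self.individuals = np.array([f"ind{i + 1}" for i in range(n)])
        else:
            self.individuals = np.asarray(self.individuals, dtype=object)
        if self.markers is None:
            self.markers = np.array([f"snp{j + 1}" for j in range(m)])
        else:
            self.markers = np.asarray(self.markers, dtype=object)
        if len(self.individuals) != n:
            raise ValueError("individual labels do not match matrix rows")
        if len(self.markers) != m:
            raise ValueError("marker labels do not match matrix columns")
        observed = ~np.isnan(self.dosages)
        vals = self.dosages[observed]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def select_markers(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask_or_idx],
            individuals=self.individuals,
            markers=self.markers[mask_or_idx],
        )

    def select_individuals(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[mask_or_idx, :],
            individuals=self.individuals[mask_or_idx],
            markers=self.markers,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals, columns=self.markers)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            df.to_numpy(dtype=float),
            individuals=df.index.to_numpy(dtype=object),
            markers=df.columns.to_numpy(dtype=object),
        )


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and coerce column dtypes."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    out["individual"] = out["individual"].astype(str)
    out["harvest"] = out["harvest"].astype(int)
    out["block"] = out["block"].astype(int)
    out["value"] = out["value"].astype(float)
    if out["value"].isna().any():
        raise ValueError("phenotype values contain NaN")
    return out


def individual_means(df: pd.DataFrame, harvest: int | None = None) -> pd.Series:
    """Per-individual mean phenotype, optionally restricted to one harvest.

    Averaging across blocks (and harvests, when ``harvest`` is None) gives
    the entry-mean phenotype used for predictive-ability correlations.
    """
    sub = df if harvest is None else df[df["harvest"] == harvest]
    if sub.empty:
        raise ValueError(f"no phenotype records for harvest {harvest!r}")
    return sub.groupby("individual")["value"].mean()
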