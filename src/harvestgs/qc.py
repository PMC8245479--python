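"""Marker quality control: call rate, minor allele frequency, imputation
and standardization of the dosage matrix into the Z incidence matrix.

The MAF critical level follows the population-size rule 1/sqrt(2N): with
N genotyped individuals, alleles rarer than that are expected fewer than
once per sqrt(2N) chromosomes and carry no usable signal.  Filtering is
>= on call rate and strictly > on MAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCParams
from .containers import GenotypeMatrix

__all__ = [
    "QCReport",
    "DosageStandardizer",
    "maf_critical_level",
    "marker_call_rate",
    "marker_maf",
    "apply_qc",
    "impute_and_standardize",
]


def maf_critical_level(n_individuals: int) -> float:
    """Population-size critical MAF, 1/sqrt(2N)."""
    if n_individuals <= 0:
        raise ValueError("number of individuals must be positive")
    return 1.0 / np.sqrt(2.0 * n_individuals)


def marker_call_rate(column: np.ndarray) -> float:
    """Fraction of non-missing genotype calls in one marker column."""
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("empty genotype column")
    return float(np.mean(~np.isnan(col)))


def marker_maf(column: np.ndarray) -> float:
    """Minor allele frequency over the observed calls of one marker."""
    col = np.asarray(column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF of an all-missing marker")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


@dataclass
class QCReport:
    """Exclusion bookkeeping; a marker failing both rules counts in both."""

    n_input_markers: int
    n_failed_call_rate: int
    n_failed_maf: int
    n_retained: int
    call_rate_min: float
    maf_min: float
    per_marker: pd.DataFrame  # marker, call_rate, maf, retained

    def __post_init__(self) -> None:
        n_failed_any = int((~self.per_marker["retained"]).sum())
        if self.n_retained + n_failed_any != self.n_input_markers:
            raise ValueError("QC report counts do not reconcile")


def apply_qc(genotypes: GenotypeMatrix, params: QCParams) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by call rate (>=) and MAF (strict >).

    With ``maf_min="auto"`` the threshold is the critical level
    1/sqrt(2N) at the matrix's own number of individuals (or
    ``params.n_individuals`` when given).
    """
    if genotypes.n_markers == 0:
        raise ValueError("empty genotype matrix")
    D = genotypes.dosages
    n_obs = np.sum(~np.isnan(D), axis=0)
    if np.any(n_obs == 0):
        raise ValueError("all-missing marker column; remove before QC")
    call_rates = n_obs / genotypes.n_individuals
    p = np.nansum(D, axis=0) / (2.0 * n_obs)
    mafs = np.minimum(p, 1.0 - p)

    if params.maf_min == "auto":
        N = params.n_individuals or genotypes.n_individuals
        maf_min = maf_critical_level(N)
    else:
        maf_min = float(params.maf_min)

    pass_cr = call_rates >= params.call_rate_min
    pass_maf = mafs > maf_min
    retained = pass_cr & pass_maf

    report = QCReport(
        n_input_markers=genotypes.n_markers,
        n_failed_call_rate=int((~pass_cr).sum()),
        n_failed_maf=int((~pass_maf).sum()),
        n_retained=int(retained.sum()),
        call_rate_min=params.call_rate_min,
        maf_min=maf_min,
        per_marker=pd.DataFrame(
            {
                "marker": genotypes.markers,
                "call_rate": call_rates,
                "maf": mafs,
                "retained": retained,
            }
        ),
    )
    if report.n_retained == 0:
        warnings.warn("no markers survived QC", stacklevel=2)
    return genotypes.select_markers(retained), report


@dataclass
class DosageStandardizer:
    """Impute-by-marker-mean then center/scale to zero mean, unit variance.

    The variance used is the population variance (divide by n).  Fitted
    means and scales are frozen so held-out individuals can be projected
    onto the training-set standardization.
    """

    means: np.ndarray
    scales: np.ndarray
    marker_ids: np.ndarray

    @classmethod
    def fit(cls, genotypes: GenotypeMatrix) -> "DosageStandardizer":
        D = genotypes.dosages
        means = np.nanmean(D, axis=0)
        filled = np.where(np.isnan(D), means[None, :], D)
        scales = filled.std(axis=0, ddof=0)
        if np.any(scales == 0):
            bad = list(genotypes.markers[scales == 0])
            raise ValueError(
                f"zero-variance marker(s) {bad[:5]}...; run the MAF filter before standardizing"
            )
        return cls(means=means, scales=scales, marker_ids=np.asarray(genotypes.markers))

    def transform(self, genotypes: GenotypeMatrix) -> np.ndarray:
        if list(genotypes.markers) != list(self.marker_ids):
            raise ValueError("marker ids do not match the fitted standardizer")
        D = genotypes.dosages
        filled = np.where(np.isnan(D), self.means[None, :], D)
        return (filled - self.means[None, :]) / self.scales[None, :]


def impute_and_standardize(genotypes: GenotypeMatrix) -> tuple[np.ndarray, DosageStandardizer]:
    """Fit a standardizer on the matrix and return (Z, standardizer)."""
    std = DosageStandardizer.fit(genotypes)
    return std.transform(genotypes), std
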