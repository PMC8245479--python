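"""Tenfold cross-validation of genomic predictions.

Individuals are partitioned into k disjoint, size-balanced folds.  For
each fold the model — marker QC, standardization, REML variance
components and marker effects — is rebuilt from the 9/10 training
individuals only, and the held-out 1/10 are scored with their own
genotypes projected onto the training-set standardization.  Predictive
ability r_yg is the Pearson correlation between the assembled
out-of-fold GEBV and the observed individual-mean phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCParams
from .containers import GenotypeMatrix, individual_means
from .qc import DosageStandardizer, apply_qc
from .rrblup import (
    MixedModelSpec,
    VarianceComponents,
    build_design,
    estimate_variance_components,
    predict_gebv,
    solve_mme,
)

__all__ = ["FoldPlan", "CVResult", "make_folds", "cross_validate"]


@dataclass
class FoldPlan:
    """Balanced random partition of NT individuals into k folds."""

    k: int
    assignments: np.ndarray  # fold index per individual position
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        sizes = np.bincount(self.assignments, minlength=self.k)
        if len(sizes) != self.k or sizes.min() == 0:
            raise ValueError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    @property
    def n_total(self) -> int:
        return len(self.assignments)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(training index, validation index) for one fold."""
        val = self.assignments == fold
        return np.where(~val)[0], np.where(val)[0]


def make_folds(n_total: int, k: int, seed: int) -> FoldPlan:
    """Uniformly random balanced partition, deterministic given seed."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_total < k:
        raise ValueError("cannot split fewer individuals than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    assignments = np.empty(n_total, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    oof_gebv: pd.Series  # one out-of-fold prediction per individual
    r_yg: float  # may be NaN when undefined (constant inputs)
    fold_plan: FoldPlan
    per_fold: list[dict] = field(default_factory=list)
    r_yg_defined: bool = True


def _fit_fold(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    harvest: int | None,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    qc_params: QCParams | None,
    aggregate: str,
) -> tuple[np.ndarray, VarianceComponents, int]:
    """Train on ``train_idx`` individuals, return GEBV for ``val_idx``."""
    train_gm = genotypes.select_individuals(train_idx)
    if qc_params is not None:
        train_gm, _ = apply_qc(train_gm, qc_params)
    # markers monomorphic within the training rows carry no signal and
    # cannot be standardized; drop them regardless of QC settings
    poly = np.nanvar(train_gm.dosages, axis=0) > 0
    train_gm = train_gm.select_markers(poly)
    retained = np.isin(genotypes.markers, train_gm.markers)
    std = DosageStandardizer.fit(train_gm)
    Z_train = std.transform(train_gm)
    train_ids = genotypes.individuals[train_idx]
    train_pheno = pheno[pheno["individual"].isin(set(train_ids))]
    spec = build_design(train_pheno, harvest, train_ids, Z_train, aggregate=aggregate)
    spec.marker_ids = np.asarray(train_gm.markers)
    vc = estimate_variance_components(spec)
    Z_val = std.transform(genotypes.select_individuals(val_idx).select_markers(retained))
    if not np.isfinite(vc.ridge):  # zero genetic variance: all effects shrink to 0
        return np.zeros(len(val_idx)), vc, int(retained.sum())
    eff = solve_mme(spec, vc)
    return Z_val @ eff.a_hat, vc, int(retained.sum())


def cross_validate(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    harvest: int | None = None,
    k: int = 10,
    seed: int = 0,
    qc_params: QCParams | None = None,
    aggregate: str = "records",
) -> CVResult:
    """k-fold CV on one harvest (harvest=None uses the mean yield).

    QC (when ``qc_params`` is given) and standardization are re-derived
    inside each training fold; the held-out individuals never influence
    either.  Every individual receives exactly one out-of-fold GEBV.
    """
    plan = make_folds(genotypes.n_individuals, k, seed)
    oof = np.full(genotypes.n_individuals, np.nan)
    per_fold: list[dict] = []
    for fold in range(k):
        train_idx, val_idx = plan.split(fold)
        gebv_val, vc, n_markers = _fit_fold(
            genotypes, pheno, harvest, train_idx, val_idx, qc_params, aggregate
        )
        oof[val_idx] = gebv_val
        per_fold.append(
            {
                "fold": fold,
                "n_train": len(train_idx),
                "n_val": len(val_idx),
                "n_markers": n_markers,
                "sigma2_g": vc.sigma2_g,
                "sigma2_e": vc.sigma2_e,
                "h2": vc.h2,
            }
        )
    assert not np.isnan(oof).any(), "some individual was never predicted"

    oof_series = pd.Series(
        oof, index=pd.Index(genotypes.individuals, name="individual"), name="oof_gebv"
    )
    obs = individual_means(pheno, harvest).reindex(oof_series.index)
    defined = obs.std() > 0 and oof_series.std() > 0
    r_yg = float(np.corrcoef(oof_series.to_numpy(), obs.to_numpy())[0, 1]) if defined else float("nan")
    return CVResult(
        oof_gebv=oof_series,
        r_yg=r_yg,
        fold_plan=plan,
        per_fold=per_fold,
        r_yg_defined=bool(defined),
    )
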