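"""Cross-harvest model-transfer validation.

A perennial crop is harvested repeatedly from the same plants, so a
prediction model trained at one age can be scored against the genetic
merit the same individuals express at a later age.  Marker effects are
estimated from the training harvest inside the usual cross-validation
folds; each individual's out-of-fold GEBV is then correlated with its
EBV at the test harvest (a genomic BLUP from that harvest's own
phenotypes) or, optionally, with its adjusted phenotypic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCParams
from .containers import GenotypeMatrix, individual_means
from .cv import CVResult, cross_validate
from .qc import apply_qc, impute_and_standardize
from .rrblup import build_design, estimate_variance_components, solve_mme

__all__ = ["TransferResult", "compute_ebv", "transfer_accuracy"]


@dataclass
class TransferResult:
    train_harvest: int
    test_harvest: int
    transfer_accuracy: float
    target: str  # "ebv" or "phenotype"
    cv_result: CVResult
    scatter: pd.DataFrame  # individual, gebv, target value

    def __post_init__(self) -> None:
        if not (np.isnan(self.transfer_accuracy) or -1 <= self.transfer_accuracy <= 1):
            raise ValueError("transfer accuracy must be a correlation")


def compute_ebv(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    harvest: int | None,
    qc_params: QCParams | None = None,
    aggregate: str = "records",
) -> pd.Series:
    """Per-individual EBV for one harvest via genomic-relationship BLUP.

    Fits the full-data RR-BLUP model (equivalent to GBLUP with
    K = ZZ'/n) with block fixed effects and returns Z @ a_hat.
    """
    gm = genotypes
    if qc_params is not None:
        gm, _ = apply_qc(gm, qc_params)
    gm = gm.select_markers(np.nanvar(gm.dosages, axis=0) > 0)  # monomorphic: no signal
    sub = pheno if harvest is None else pheno[pheno["harvest"] == harvest]
    if sub.empty:
        raise ValueError(f"no phenotype records for harvest {harvest!r}")
    missing = set(sub["individual"]) - set(gm.individuals)
    if missing:
        raise ValueError(f"phenotyped individuals lack genotypes: {sorted(missing)[:5]}")
    Z, _ = impute_and_standardize(gm)
    spec = build_design(sub, harvest, gm.individuals, Z, aggregate=aggregate)
    vc = estimate_variance_components(spec)
    eff = solve_mme(spec, vc)
    return pd.Series(
        Z @ eff.a_hat, index=pd.Index(gm.individuals, name="individual"), name="ebv"
    )


def transfer_accuracy(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    train_harvest: int,
    test_harvest: int,
    k: int = 10,
    seed: int = 0,
    qc_params: QCParams | None = None,
    aggregate: str = "records",
    target: str = "ebv",
) -> TransferResult:
    """Train on harvest i, validate against harvest j genetic merit.

    With target="phenotype" and i == j this reduces exactly to
    :func:`harvestgs.cv.cross_validate`'s predictive ability (same folds
    for the same seed).
    """
    for h in (train_harvest, test_harvest):
        if not (pheno["harvest"] == h).any():
            raise ValueError(f"no phenotype records for harvest {h}")
    train_inds = set(pheno.loc[pheno["harvest"] == train_harvest, "individual"])
    test_inds = set(pheno.loc[pheno["harvest"] == test_harvest, "individual"])
    if not (train_inds & test_inds):
        raise ValueError("train and test harvests share no individuals")

    cvres = cross_validate(
        genotypes,
        pheno,
        harvest=train_harvest,
        k=k,
        seed=seed,
        qc_params=qc_params,
        aggregate=aggregate,
    )
    if target == "ebv":
        tgt = compute_ebv(genotypes, pheno, test_harvest, qc_params=qc_params, aggregate=aggregate)
    elif target == "phenotype":
        tgt = individual_means(pheno, test_harvest)
    else:
        raise ValueError("target must be 'ebv' or 'phenotype'")

    joined = pd.concat([cvres.oof_gebv, tgt.rename("target")], axis=1, join="inner").dropna()
    if joined["oof_gebv"].std() > 0 and joined["target"].std() > 0:
        acc = float(np.corrcoef(joined["oof_gebv"], joined["target"])[0, 1])
    else:
        acc = float("nan")
    return TransferResult(
        train_harvest=train_harvest,
        test_harvest=test_harvest,
        transfer_accuracy=acc,
        target=target,
        cv_result=cvres,
        scatter=joined.reset_index().rename(columns={"oof_gebv": "gebv"}),
    )
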