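"""Derived selection statistics.

From a predictive ability r_yg and heritability estimates these
operations produce the decision-relevant quantities of a genomic
selection programme:

* selective accuracy       r_gg_hat = r_yg / sqrt(h2_a * h2_g)
* implied number of QTL    n_qtl    = (1 - q) * N * h2_g / q
* individuals required     Ni       = q * n_qtl / ((1 - q) * h2_g)
* phenotypic accuracy      r_yy_hat = sqrt(1 - PEV / sigma2_g)
* efficiency vs phenotypic selection and its percentage form
  IRPS = (r_gg_hat * Tf) / (r_yy_hat * Tgws) - 1

The ``scale`` flag controls whether the observed/desired value q enters
the QTL-count and population-size formulas as a squared correlation
(scale="accuracy", the formulas as printed) or directly as a
reliability (scale="reliability", which reproduces the internal ratios
of published required-population-size tables).  Ni and n_qtl are exact
algebraic inverses of each other at any fixed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HeritabilityEstimates",
    "MetricsReport",
    "gws_accuracy",
    "n_qtl_estimate",
    "individuals_required",
    "phenotypic_accuracy",
    "irps",
    "narrow_and_genomic_h2",
    "ni_table",
    "phenotypic_selection_accuracy",
]


@dataclass
class HeritabilityEstimates:
    h2_a: float  # narrow-sense heritability
    h2_g: float  # genomic (marker-captured) heritability

    def __post_init__(self) -> None:
        for name in ("h2_a", "h2_g"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _q(value: float, scale: str) -> float:
    if scale == "accuracy":
        return value**2
    if scale == "reliability":
        return value
    raise ValueError("scale must be 'accuracy' or 'reliability'")


def gws_accuracy(r_yg: float, h: HeritabilityEstimates) -> float:
    """Selective accuracy of genomic selection.

    Values above 1 (possible when the heritability product understates
    the signal actually captured) are clamped to 1 with a warning.
    """
    prod = h.h2_a * h.h2_g
    if prod <= 0:
        raise ValueError("h2_a * h2_g must be positive")
    r = r_yg / np.sqrt(prod)
    if r > 1:
        warnings.warn(f"accuracy {r:.3f} > 1 clamped to 1", stacklevel=2)
        return 1.0
    return float(r)


def n_qtl_estimate(r_obs: float, n_individuals: int, h2_g: float, scale: str = "reliability") -> float:
    """Number of QTL implied by an observed accuracy in a population of N."""
    if not 0 < r_obs < 1:
        raise ValueError("observed accuracy must lie strictly in (0, 1)")
    if n_individuals <= 0 or h2_g <= 0:
        raise ValueError("N and h2_g must be positive")
    q = _q(r_obs, scale)
    return (1 - q) * n_individuals * h2_g / q


def individuals_required(
    r_desired: float,
    n_qtl: float,
    h2_g: float,
    scale: str = "reliability",
    rounding: str = "nearest",
) -> int:
    """Population size needed to reach a desired selective accuracy."""
    if not 0 < r_desired < 1:
        raise ValueError("desired accuracy must lie strictly in (0, 1)")
    if n_qtl <= 0 or h2_g <= 0:
        raise ValueError("n_qtl and h2_g must be positive")
    q = _q(r_desired, scale)
    ni = q * n_qtl / ((1 - q) * h2_g)
    if rounding == "nearest":
        return int(round(ni))
    if rounding == "ceil":
        return int(np.ceil(ni))
    raise ValueError("rounding must be 'nearest' or 'ceil'")


def ni_table(
    desired: list[float] | tuple[float, ...],
    n_qtl: float,
    h2_g: float,
    scale: str = "reliability",
    rounding: str = "nearest",
) -> pd.DataFrame:
    """Required-population-size table over a grid of desired accuracies."""
    rows = [
        {
            "desired_accuracy": r,
            "individuals_required": individuals_required(r, n_qtl, h2_g, scale, rounding),
        }
        for r in desired
    ]
    return pd.DataFrame(rows)


def phenotypic_accuracy(pev: float, sigma2_g_pop: float) -> float:
    """Accuracy of phenotype-based selection from prediction-error variance."""
    if sigma2_g_pop <= 0:
        raise ValueError("genotypic variance must be positive")
    if not 0 <= pev <= sigma2_g_pop:
        raise ValueError("PEV must lie in [0, sigma2_g]")
    return float(np.sqrt(1.0 - pev / sigma2_g_pop))


def irps(r_g_hat: float, r_y_hat: float, t_phenotypic: float, t_gws: float) -> tuple[float, float]:
    """(efficiency, IRPS %) of genomic over phenotypic selection.

    Efficiency compares genetic gain per unit time; IRPS is the
    percentage increase, (efficiency - 1) * 100.  Only the ratio
    t_phenotypic / t_gws matters.
    """
    if min(r_g_hat, r_y_hat, t_phenotypic, t_gws) <= 0:
        raise ValueError("accuracies and cycle times must be positive")
    eff = (r_g_hat * t_phenotypic) / (r_y_hat * t_gws)
    return float(eff), float((eff - 1.0) * 100.0)


def narrow_and_genomic_h2(vc, h2_g: float | None = None) -> HeritabilityEstimates:
    """Heritabilities from variance components.

    h2_a = sigma2_a / sigma2_p.  The marker-captured h2_g defaults to the
    same genomic ratio but may be supplied independently, since the two
    are only distinguishable with an additional (pedigree) estimate of
    total additive variance.
    """
    if vc.sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    h2_a = min(max(vc.sigma2_a / vc.sigma2_p, 0.0), 1.0)
    if h2_g is None:
        h2_g = min(max(vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e), 0.0), 1.0)
    return HeritabilityEstimates(h2_a=h2_a, h2_g=h2_g)


def phenotypic_selection_accuracy(
    pheno: pd.DataFrame, harvest: int | None = None
) -> tuple[float, float, float]:
    """(r_yy_hat, mean PEV, sigma2_g) from the phenotypic mixed model.

    Fits y = Xb + Wu + e with u an independent genetic effect per
    individual (estimable here because every individual is replicated
    across blocks), X = intercept + drop-first block dummies.  PEV is
    sigma2_e times the per-individual diagonal of the inverse mixed-model
    coefficient matrix, averaged over individuals.
    """
    from .rrblup import _reml_profile  # shared spectral REML core

    sub = pheno if harvest is None else pheno[pheno["harvest"] == harvest]
    if sub.empty:
        raise ValueError(f"no phenotype records for harvest {harvest!r}")
    inds = np.array(sorted(sub["individual"].unique()))
    if len(sub) <= len(inds):
        raise ValueError("phenotypic accuracy needs replicated records per individual")
    ind_pos = {v: i for i, v in enumerate(inds)}
    rows = np.array([ind_pos[v] for v in sub["individual"]])
    nrec, nind = len(sub), len(inds)
    W = np.zeros((nrec, nind))
    W[np.arange(nrec), rows] = 1.0
    cols = [np.ones(nrec)]
    for h in sorted(sub["harvest"].unique())[1:]:
        cols.append((sub["harvest"] == h).to_numpy(dtype=float))
    for b in sorted(sub["block"].unique())[1:]:
        cols.append((sub["block"] == b).to_numpy(dtype=float))
    X = np.column_stack(cols)
    y = sub["value"].to_numpy()

    s2u, s2e, _ = _reml_profile(y, X, W, k_scale=1.0)
    if s2u <= 0:
        raise ValueError("estimated genotypic variance is zero; accuracy undefined")
    lam = s2e / s2u
    p = X.shape[1]
    C = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(nind)]])
    Cinv = np.linalg.inv(C)
    pev = s2e * np.diag(Cinv)[p:]
    pev = np.clip(pev, 0.0, s2u)
    r_ind = np.sqrt(1.0 - pev / s2u)
    return float(r_ind.mean()), float(pev.mean()), float(s2u)


@dataclass
class MetricsReport:
    """Bundle of selection statistics for one harvest (or the mean yield)."""

    r_yg: float
    heritabilities: HeritabilityEstimates
    r_g_hat: float
    r_y_hat: float
    pev: float
    sigma2_g_pop: float
    n_qtl: float
    ni: pd.DataFrame
    t_phenotypic: float
    t_gws: float
    efficiency: float
    irps_percent: float
    scale: str = "reliability"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r_yg": self.r_yg,
            "h2_a": self.heritabilities.h2_a,
            "h2_g": self.heritabilities.h2_g,
            "gws_accuracy": self.r_g_hat,
            "phenotypic_accuracy": self.r_y_hat,
            "pev": self.pev,
            "sigma2_g_pop": self.sigma2_g_pop,
            "n_qtl": self.n_qtl,
            "ni_table": self.ni.to_dict(orient="records"),
            "t_phenotypic": self.t_phenotypic,
            "t_gws": self.t_gws,
            "efficiency": self.efficiency,
            "irps_percent": self.irps_percent,
            "scale": self.scale,
            **self.extras,
        }


def build_metrics_report(
    r_yg: float,
    h: HeritabilityEstimates,
    n_individuals: int,
    pheno: pd.DataFrame,
    harvest: int | None,
    t_phenotypic: float = 2.0,
    t_gws: float = 1.0,
    desired: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    scale: str = "reliability",
) -> MetricsReport:
    """Assemble the full per-harvest selection-metrics report."""
    r_g_hat = gws_accuracy(r_yg, h)
    r_y_hat, pev, s2g_pop = phenotypic_selection_accuracy(pheno, harvest)
    nq = n_qtl_estimate(min(max(r_g_hat, 1e-6), 1 - 1e-9), n_individuals, h.h2_g, scale)
    table = ni_table(list(desired), nq, h.h2_g, scale)
    eff, pct = irps(max(r_g_hat, 1e-12), max(r_y_hat, 1e-12), t_phenotypic, t_gws)
    return MetricsReport(
        r_yg=r_yg,
        heritabilities=h,
        r_g_hat=r_g_hat,
        r_y_hat=r_y_hat,
        pev=pev,
        sigma2_g_pop=s2g_pop,
        n_qtl=nq,
        ni=table,
        t_phenotypic=t_phenotypic,
        t_gws=t_gws,
        efficiency=eff,
        irps_percent=pct,
        scale=scale,
    )
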