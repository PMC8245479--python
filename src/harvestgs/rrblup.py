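"""RR-BLUP core: REML variance components, mixed-model equations, GEBV.

Model
-----
    y = X b + Z a + e,   a ~ N(0, I s2_m),   e ~ N(0, I s2_e)

with Z the standardized dosage matrix (columns mean 0, variance 1).  The
total genetic variance is s2_g = n_markers * s2_m, so the equivalent
individual-level (GBLUP) model has genetic covariance

    Var(Za) = Z Z' s2_m = K s2_g,   K = Z Z' / n_markers.

Variance components are estimated by REML on this equivalent model:
after projecting out the fixed effects, a thin SVD of the projected Z
diagonalizes K on the residual space, and the REML log-likelihood is
profiled over the single ratio delta = s2_e / s2_g.  Marker effects then
come from Henderson's mixed-model equations with ridge
lambda = s2_e / (s2_g / n_markers) = n_markers * delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "MarkerEffects",
    "GEBVSet",
    "estimate_variance_components",
    "solve_mme",
    "predict_gebv",
]

_SV_TOL = 1e-10


@dataclass
class MixedModelSpec:
    """Design matrices of one RR-BLUP fit; rows are records."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    marker_ids: np.ndarray | None = None
    fixed_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("row counts of y, X and Z must agree")
        if self.marker_ids is not None:
            self.marker_ids = np.asarray(self.marker_ids)
            if len(self.marker_ids) != self.Z.shape[1]:
                raise ValueError("marker_ids length must equal Z columns")


@dataclass
class VarianceComponents:
    sigma2_m: float  # per-marker effect variance
    sigma2_g: float  # total genetic variance, n_markers * sigma2_m
    sigma2_e: float  # residual variance
    sigma2_a: float  # additive variance (= sigma2_g by default)
    sigma2_p: float  # phenotypic variance at the record level
    ridge: float  # lambda = sigma2_e / (sigma2_g / n_markers)
    n_markers: int
    reml_trace: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        total = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / total if total > 0 else float("nan")


@dataclass
class MarkerEffects:
    beta_hat: np.ndarray
    a_hat: np.ndarray
    marker_ids: np.ndarray | None = None
    fixed_names: Sequence[str] | None = None


@dataclass
class GEBVSet:
    """Per-individual genomic estimated breeding values with provenance."""

    gebv: pd.Series
    provenance: dict = field(default_factory=dict)


def _reml_profile(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    k_scale: float,
    bounds: tuple[float, float] = (1e-6, 1e6),
    n_grid: int = 41,
) -> tuple[float, float, pd.DataFrame]:
    """REML for Var(y) = s2_g * Z Z'/k_scale + s2_e * I.

    Returns (s2_g, s2_e, trace).  The profile over delta = s2_e/s2_g is
    evaluated on a log grid and refined by bounded scalar minimization.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    Q, _ = np.linalg.qr(X)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    SZ = Z - Q @ (Q.T @ Z)
    Sy = y - Q @ (Q.T @ y)
    U, s, _ = np.linalg.svd(SZ, full_matrices=False)
    keep = s > _SV_TOL * max(1.0, s[0] if s.size else 0.0)
    xi = (s[keep] ** 2) / k_scale  # nonzero eigenvalues of S K S
    eta2 = (U[:, keep].T @ Sy) ** 2
    yy = float(Sy @ Sy)
    if yy <= 1e-290:  # phenotype fully explained by fixed effects
        return 0.0, 0.0, pd.DataFrame({"log_delta": [], "criterion": []})
    rest = max(yy - float(eta2.sum()), 0.0)  # mass on zero-eigenvalue space
    df = n - p
    n_zero = df - int(keep.sum())

    def crit(log_delta: float) -> float:
        d = np.exp(log_delta)
        quad = float(np.sum(eta2 / (xi + d))) + rest / d
        logdet = float(np.sum(np.log(xi + d))) + n_zero * np.log(d)
        return df * np.log(quad) + logdet

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([crit(g) for g in grid])
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(crit, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
    best = res.x if res.fun <= vals[i] else grid[i]

    delta = float(np.exp(best))
    quad = float(np.sum(eta2 / (xi + delta))) + rest / delta
    sigma2_g = quad / df
    sigma2_e = delta * sigma2_g
    trace = pd.DataFrame({"log_delta": grid, "criterion": vals})
    return sigma2_g, sigma2_e, trace


def estimate_variance_components(
    spec: MixedModelSpec,
    sigma2_a: float | None = None,
    sigma2_p: float | None = None,
) -> VarianceComponents:
    """REML estimates of the genetic and residual variance for one fit.

    By default the additive variance is identified with the genomic
    sigma2_g and the phenotypic variance with sigma2_g + sigma2_e at the
    record level; pass user-supplied components to override (e.g. when
    they come from a separate pedigree analysis).
    """
    m = spec.Z.shape[1]
    s2g, s2e, trace = _reml_profile(spec.y, spec.X, spec.Z, k_scale=m)
    ridge = np.inf if s2g == 0 else s2e * m / s2g
    return VarianceComponents(
        sigma2_m=s2g / m,
        sigma2_g=s2g,
        sigma2_e=s2e,
        sigma2_a=s2g if sigma2_a is None else sigma2_a,
        sigma2_p=s2g + s2e if sigma2_p is None else sigma2_p,
        ridge=ridge,
        n_markers=m,
        reml_trace=trace,
    )


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents) -> MarkerEffects:
    """Solve Henderson's equations for (beta_hat, a_hat).

        [ X'X      X'Z          ] [beta]   [X'y]
        [ Z'X      Z'Z + I*l    ] [a   ] = [Z'y]
    """
    lam = vc.ridge
    if not lam > 0:
        raise ValueError("ridge parameter must be positive")
    X, Z, y = spec.X, spec.Z, spec.y
    p, m = X.shape[1], Z.shape[1]
    if np.linalg.matrix_rank(X) < p:
        # name the aliased columns via pivoted QR
        _, _, piv = sla.qr(X, pivoting=True)
        r = np.linalg.matrix_rank(X)
        names = spec.fixed_names or [f"x{j}" for j in range(p)]
        aliased = [names[j] for j in piv[r:]]
        raise ValueError(f"rank-deficient fixed-effect design; aliased columns: {aliased}")
    C = np.empty((p + m, p + m))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z
    C[p:, p:][np.diag_indices(m)] += lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    cho = sla.cho_factor(C, lower=True)
    sol = sla.cho_solve(cho, rhs)
    resid = C @ sol - rhs
    rel = np.linalg.norm(resid) / max(np.linalg.norm(rhs), 1e-300)
    if rel > 1e-8:
        raise RuntimeError(f"mixed-model equations solved to only {rel:.2e} relative residual")
    return MarkerEffects(
        beta_hat=sol[:p],
        a_hat=sol[p:],
        marker_ids=spec.marker_ids,
        fixed_names=spec.fixed_names,
    )


def predict_gebv(
    Z: np.ndarray,
    effects: MarkerEffects,
    individuals: Sequence | None = None,
    marker_ids: Sequence | None = None,
    provenance: dict | None = None,
) -> GEBVSet:
    """GEBV g_hat = Z @ a_hat, aligning marker columns by id when given."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    a = effects.a_hat
    if marker_ids is not None and effects.marker_ids is not None:
        mine, theirs = list(marker_ids), list(effects.marker_ids)
        if mine != theirs:
            sym = sorted(set(mine) ^ set(theirs))
            if sym:
                raise ValueError(f"marker sets differ; symmetric difference: {sym[:10]}")
            order = [mine.index(t) for t in theirs]
            Z = Z[:, order]
    if Z.shape[1] != a.shape[0]:
        raise ValueError("Z columns and marker effects do not align")
    g = Z @ a
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(Z.shape[0])]
    return GEBVSet(
        gebv=pd.Series(g, index=pd.Index(individuals, name="individual"), name="gebv"),
        provenance=provenance or {},
    )


def build_design(
    pheno: pd.DataFrame,
    harvest: int | None,
    individuals: np.ndarray,
    Z_ind: np.ndarray,
    aggregate: str = "records",
) -> MixedModelSpec:
    """Assemble (y, X, Z) for one harvest (or, with None, the mean yield).

    aggregate="records" keeps one row per plot with intercept +
    drop-first block dummies (blocks entered as fixed effects; a
    drop-first harvest factor is added when records are pooled across
    harvests); aggregate="means" collapses to individual means with an
    intercept only.  ``Z_ind`` holds one standardized row per entry of
    ``individuals``.
    """
    sub = pheno if harvest is None else pheno[pheno["harvest"] == harvest]
    if sub.empty:
        raise ValueError(f"no phenotype records for harvest {harvest!r}")
    idx = {ind: i for i, ind in enumerate(individuals)}
    missing = set(sub["individual"]) - set(idx)
    if missing:
        raise ValueError(f"phenotyped individuals lack genotypes: {sorted(missing)[:5]}")

    if aggregate == "means":
        means = sub.groupby("individual")["value"].mean()
        rows = [idx[i] for i in means.index]
        y = means.to_numpy()
        X = np.ones((len(y), 1))
        names = ["intercept"]
        Z = Z_ind[rows]
    elif aggregate == "records":
        rows = [idx[i] for i in sub["individual"]]
        y = sub["value"].to_numpy()
        cols = [np.ones(len(y))]
        names = ["intercept"]
        for h in sorted(sub["harvest"].unique())[1:]:
            cols.append((sub["harvest"] == h).to_numpy(dtype=float))
            names.append(f"harvest{h}")
        for b in sorted(sub["block"].unique())[1:]:
            cols.append((sub["block"] == b).to_numpy(dtype=float))
            names.append(f"block{b}")
        X = np.column_stack(cols)
        Z = Z_ind[rows]
    else:
        raise ValueError("aggregate must be 'records' or 'means'")
    return MixedModelSpec(y=y, X=X, Z=Z, fixed_names=names)
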