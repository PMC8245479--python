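"""Configuration objects and YAML loading.

Defaults mirror the study population this package was built around: a
cross among 42 parents yielding 386 progeny, ~800 SNPs after quality
control, grain yield scored over three harvests in a randomized block
design with six replicates, and narrow-sense heritabilities around
0.18-0.25 per harvest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

#: Per-harvest grain-yield means (g/plant) used as simulator defaults.
DEFAULT_HARVEST_MEANS = (173.76, 760.85, 1075.52)

#: Default genetic correlation across the three harvests: adjacent later
#: harvests correlate more strongly than the juvenile first harvest,
#: reproducing the pattern where models transfer better 2->3 than 1->2/3.
DEFAULT_GENETIC_CORR = (
    (1.0, 0.40, 0.30),
    (0.40, 1.0, 0.70),
    (0.30, 0.70, 1.0),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic breeding-population generator.

    h2_per_harvest is the narrow-sense heritability of single plot
    records, sigma_g^2 / (sigma_g^2 + sigma_e^2); block effects enter as
    fixed effects downstream and are excluded from this denominator.
    genetic_sd (trait units, g/plant) fixes the genetic standard
    deviation each harvest's true breeding values are scaled to.
    """

    n_parents: int = 42
    n_progeny: int = 386
    n_markers: int = 811
    n_qtl_sim: int = 400
    n_harvests: int = 3
    h2_per_harvest: Sequence[float] = (0.18, 0.19, 0.20)
    genetic_corr: Sequence[Sequence[float]] = DEFAULT_GENETIC_CORR
    n_blocks: int = 6
    block_sd: float = 30.0
    genetic_sd: float = 60.0
    maf_floor: float = 0.05
    missing_rate: float = 0.02
    harvest_means: Sequence[float] = DEFAULT_HARVEST_MEANS
    seed: int = 0

    def __post_init__(self) -> None:
        self.h2_per_harvest = tuple(float(h) for h in self.h2_per_harvest)
        self.harvest_means = tuple(float(m) for m in self.harvest_means)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("n_parents", "n_progeny", "n_markers", "n_qtl_sim", "n_harvests", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_parents < 2:
            raise ValueError("n_parents must be at least 2")
        if self.n_qtl_sim > self.n_markers:
            raise ValueError("n_qtl_sim cannot exceed n_markers")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.h2_per_harvest) != self.n_harvests:
            raise ValueError("h2_per_harvest length must equal n_harvests")
        if any(not 0 < h <= 1 for h in self.h2_per_harvest):
            raise ValueError("heritabilities must lie in (0, 1]")
        if len(self.harvest_means) != self.n_harvests:
            raise ValueError("harvest_means length must equal n_harvests")
        if self.block_sd < 0 or self.genetic_sd <= 0:
            raise ValueError("block_sd must be >= 0 and genetic_sd > 0")
        C = self.genetic_corr
        if C.shape != (self.n_harvests, self.n_harvests):
            raise ValueError("genetic_corr must be n_harvests x n_harvests")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(C)) < -1e-8:
            raise ValueError("genetic_corr must be positive semi-definite")
        if np.any(np.abs(C) > 1 + 1e-10):
            raise ValueError("genetic_corr entries must lie in [-1, 1]")


@dataclass
class QCParams:
    """Marker quality-control thresholds.

    maf_min="auto" applies the population-size critical level 1/sqrt(2N).
    Call rate is filtered with >= (a marker exactly at the threshold is
    kept); MAF with strict > (a marker exactly at the threshold is
    dropped).
    """

    call_rate_min: float = 0.95
    maf_min: float | str = "auto"
    n_individuals: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must lie in (0, 1]")
        if isinstance(self.maf_min, str):
            if self.maf_min != "auto":
                raise ValueError("maf_min must be a fraction or 'auto'")
        elif not 0 <= float(self.maf_min) < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.n_individuals is not None and self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate -> qc -> cv -> metrics -> transfer)."""

    simulation: SimulationConfig | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    aggregate: str = "records"  # "records" (block fixed effects) or "means"
    k_folds: int = 10
    seed: int = 0
    t_phenotypic: float = 2.0  # years per phenotypic selection cycle
    t_gws: float = 1.0  # years per genomic selection cycle
    desired_accuracies: Sequence[float] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    ni_scale: str = "reliability"  # Eq-scale flag: "reliability" or "accuracy"
    output_dir: str = "harvestgs_run"

    def __post_init__(self) -> None:
        has_paths = self.genotype_path is not None and self.phenotype_path is not None
        if self.simulation is not None and has_paths:
            raise ValueError("give either a simulation config or input paths, not both")
        if self.simulation is None and not has_paths:
            raise ValueError("one of simulation config or genotype+phenotype paths required")
        if self.aggregate not in ("records", "means"):
            raise ValueError("aggregate must be 'records' or 'means'")
        if self.ni_scale not in ("reliability", "accuracy"):
            raise ValueError("ni_scale must be 'reliability' or 'accuracy'")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.t_phenotypic <= 0 or self.t_gws <= 0:
            raise ValueError("cycle times must be positive")


def _build(cls, data: dict[str, Any]):
    return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    kwargs = dict(raw)
    if "simulation" in kwargs and kwargs["simulation"] is not None:
        kwargs["simulation"] = _build(SimulationConfig, kwargs["simulation"])
    if "qc" in kwargs and kwargs["qc"] is not None:
        kwargs["qc"] = _build(QCParams, kwargs["qc"])
    return _build(RunConfig, kwargs)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _build(SimulationConfig, raw)
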