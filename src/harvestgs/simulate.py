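"""Synthetic breeding-population generator.

Emulates the data-generating process the downstream analysis assumes: a
set of outbred parents genotyped at unlinked biallelic SNPs, progeny
produced by Mendelian gamete sampling under a balanced round-robin
crossing plan, and a quantitative trait measured over repeated harvests
in a randomized block design.  Causal marker effects are drawn jointly
across harvests from a multivariate normal whose correlation matrix is
the configured genotype-by-harvest genetic correlation, so the
cross-harvest transferability of prediction models can be dialled in and
recovered.

Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import GenotypeMatrix

__all__ = ["GenotypeSimResult", "TrueValues", "simulate_genotypes", "simulate_phenotypes"]


@dataclass
class GenotypeSimResult:
    """Genotypes plus the simulation-time bookkeeping needed for checks.

    parent_freqs are the allele frequencies markers were sampled at;
    expected_progeny_freqs are the frequencies implied by the realized
    parent genotypes and the crossing plan (the Mendelian expectation the
    progeny frequencies converge to as family sizes grow).
    """

    genotypes: GenotypeMatrix
    parent_assignments: pd.DataFrame  # progeny, sire, dam
    parent_dosages: np.ndarray  # n_parents x n_markers, complete
    parent_freqs: np.ndarray  # sampling frequencies per marker
    expected_progeny_freqs: np.ndarray


@dataclass
class TrueValues:
    """Ground truth emitted alongside simulated phenotypes."""

    true_breeding_values: pd.DataFrame  # individuals x harvests
    causal_effects: pd.DataFrame  # markers x harvests (zero rows = non-causal)
    parent_assignments: pd.DataFrame


def _crossing_plan(n_parents: int, n_progeny: int) -> np.ndarray:
    """Round-robin parent pairs with progeny split as evenly as possible.

    Cross c mates parent c with parent (c+1) mod P; the first
    ``n_progeny mod P`` crosses receive one extra progeny.
    """
    pairs = [(c, (c + 1) % n_parents) for c in range(n_parents)]
    base, extra = divmod(n_progeny, n_parents)
    out = []
    for c, (s, d) in enumerate(pairs):
        for _ in range(base + (1 if c < extra else 0)):
            out.append((s, d))
    return np.array(out[:n_progeny], dtype=int)


def _gametes(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per (progeny, marker) from the given parent genotypes."""
    u = rng.random(parent_geno.shape)
    return (parent_geno == 2).astype(float) + ((parent_geno == 1) & (u < 0.5))


def simulate_genotypes(config: SimulationConfig) -> GenotypeSimResult:
    """Simulate parent and progeny genotypes.

    Parents are drawn per marker from Hardy-Weinberg proportions at
    allele frequencies uniform on [maf_floor, 1 - maf_floor]; progeny
    inherit one Mendelian gamete from each parent of their cross.
    Missing calls are masked uniformly at random at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    P, n, m = config.n_parents, config.n_progeny, config.n_markers

    freqs = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=m)
    parents = rng.binomial(2, freqs[None, :], size=(P, m)).astype(float)

    plan = _crossing_plan(P, n)
    sires, dams = plan[:, 0], plan[:, 1]
    progeny = _gametes(parents[sires], rng) + _gametes(parents[dams], rng)

    expected = (parents[sires] + parents[dams]).mean(axis=0) / 4.0

    dosages = progeny.copy()
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    individuals = np.array([f"ind{i + 1}" for i in range(n)], dtype=object)
    markers = np.array([f"snp{j + 1}" for j in range(m)], dtype=object)
    gm = GenotypeMatrix(dosages, individuals=individuals, markers=markers)
    assignments = pd.DataFrame(
        {
            "progeny": individuals,
            "sire": [f"parent{s + 1}" for s in sires],
            "dam": [f"parent{d + 1}" for d in dams],
        }
    )
    return GenotypeSimResult(gm, assignments, parents, freqs, expected)


def _psd_sqrt(corr: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerating singular correlation matrices."""
    w, V = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w) @ V.T


def simulate_phenotypes(
    sim: GenotypeSimResult, config: SimulationConfig
) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate plot records for every individual x harvest x block.

    Per-harvest true breeding values are centered-dosage x effect sums
    over the causal markers, rescaled so each harvest's genetic SD equals
    ``genetic_sd`` exactly; residual SD per harvest is then set so the
    expected plot-record heritability equals ``h2_per_harvest``.  Block
    effects are drawn once per (harvest, block) with SD ``block_sd``.
    Missing genotype calls are imputed internally by marker mean before
    computing breeding values.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gm = sim.genotypes
    n, m, H = gm.n_individuals, gm.n_markers, config.n_harvests

    G = gm.dosages.copy()
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    Gc = G - G.mean(axis=0)

    causal = np.sort(rng.choice(m, size=config.n_qtl_sim, replace=False))
    L = _psd_sqrt(config.genetic_corr)
    raw_effects = rng.standard_normal((config.n_qtl_sim, H)) @ L.T
    tbv = Gc[:, causal] @ raw_effects  # n x H

    sd = tbv.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate genetic variance; increase n_qtl_sim or n_progeny")
    scale = config.genetic_sd / sd
    tbv = tbv * scale
    effects = np.zeros((m, H))
    effects[causal] = raw_effects * scale

    sigma_g2 = config.genetic_sd**2
    records = []
    for h in range(H):
        h2 = config.h2_per_harvest[h]
        sigma_e = np.sqrt(sigma_g2 * (1 - h2) / h2) if h2 < 1 else 0.0
        block_eff = rng.normal(0.0, config.block_sd, size=config.n_blocks)
        for b in range(config.n_blocks):
            eps = rng.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
            records.append(
                pd.DataFrame(
                    {
                        "individual": gm.individuals,
                        "harvest": h + 1,
                        "block": b + 1,
                        "value": config.harvest_means[h] + tbv[:, h] + block_eff[b] + eps,
                    }
                )
            )
    pheno = pd.concat(records, ignore_index=True)

    harvests = [f"harvest{h + 1}" for h in range(H)]
    truth = TrueValues(
        true_breeding_values=pd.DataFrame(tbv, index=gm.individuals, columns=harvests),
        causal_effects=pd.DataFrame(effects, index=gm.markers, columns=harvests),
        parent_assignments=sim.parent_assignments,
    )
    return pheno, truth
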