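"""Synthetic breeding-population generator."""

import numpy as np
import pandas as pd
import pytest

from harvestgs.config import SimulationConfig
from harvestgs.simulate import simulate_genotypes, simulate_phenotypes


def _cfg(**kw):
    base = dict(
        n_parents=10, n_progeny=200, n_markers=200, n_qtl_sim=100,
        n_harvests=1, h2_per_harvest=(0.3,), genetic_corr=((1.0,),),
        n_blocks=2, block_sd=5.0, harvest_means=(50.0,), missing_rate=0.0, seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_deterministic_given_seed(self):
        a = simulate_genotypes(_cfg(missing_rate=0.05))
        b = simulate_genotypes(_cfg(missing_rate=0.05))
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.parent_assignments, b.parent_assignments)

    def test_different_seed_differs(self):
        a = simulate_genotypes(_cfg(seed=1))
        b = simulate_genotypes(_cfg(seed=2))
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages)

    def test_zero_missing_rate_fully_observed(self):
        sim = simulate_genotypes(_cfg(missing_rate=0.0))
        assert not np.isnan(sim.genotypes.dosages).any()

    def test_missing_rate_masks_entries(self):
        sim = simulate_genotypes(_cfg(missing_rate=0.1))
        frac = np.isnan(sim.genotypes.dosages).mean()
        assert 0.05 < frac < 0.15

    def test_each_progeny_has_two_parents_from_pool(self):
        sim = simulate_genotypes(_cfg())
        pa = sim.parent_assignments
        assert len(pa) == 200
        parents = {f"parent{i + 1}" for i in range(10)}
        assert set(pa["sire"]) <= parents and set(pa["dam"]) <= parents
        assert (pa["sire"] != pa["dam"]).all()

    def test_balanced_crossing_plan(self):
        sim = simulate_genotypes(_cfg(n_progeny=203))
        counts = sim.parent_assignments.groupby(["sire", "dam"]).size()
        assert counts.max() - counts.min() <= 1

    def test_progeny_frequencies_track_parental_means(self):
        """Law of large numbers: at 10,000 progeny the realized allele
        frequency sits within +-0.03 of the Mendelian expectation from
        the parent genotypes for at least 95% of markers."""
        cfg = _cfg(n_progeny=10_000, n_markers=300, maf_floor=0.05)
        sim = simulate_genotypes(cfg)
        freq = sim.genotypes.dosages.mean(axis=0) / 2.0
        close = np.abs(freq - sim.expected_progeny_freqs) <= 0.03
        assert close.mean() >= 0.95

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            _cfg(n_parents=1)
        with pytest.raises(ValueError):
            _cfg(maf_floor=0.5)
        with pytest.raises(ValueError):
            _cfg(missing_rate=1.0)


class TestPhenotypes:
    def test_no_noise_limit_is_exact(self):
        cfg = _cfg(h2_per_harvest=(1.0,), block_sd=0.0, n_blocks=2)
        sim = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(sim, cfg)
        tbv = truth.true_breeding_values["harvest1"]
        for _, row in pheno.sample(50, random_state=0).iterrows():
            assert row["value"] == pytest.approx(50.0 + tbv[row["individual"]], abs=1e-9)

    def test_deterministic_given_seed(self):
        cfg = _cfg()
        sim = simulate_genotypes(cfg)
        p1, t1 = simulate_phenotypes(sim, cfg)
        p2, t2 = simulate_phenotypes(sim, cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1.true_breeding_values, t2.true_breeding_values)

    def test_one_record_per_individual_harvest_block(self):
        cfg = _cfg(n_harvests=2, h2_per_harvest=(0.3, 0.3),
                   genetic_corr=((1.0, 0.5), (0.5, 1.0)), harvest_means=(50.0, 60.0),
                   n_blocks=3)
        sim = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(sim, cfg)
        counts = pheno.groupby(["individual", "harvest", "block"]).size()
        assert (counts == 1).all()
        assert len(pheno) == 200 * 2 * 3

    def test_noncausal_markers_have_zero_effect(self):
        cfg = _cfg(n_qtl_sim=40)
        sim = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(sim, cfg)
        nonzero = (truth.causal_effects != 0).any(axis=1).sum()
        assert nonzero == 40

    @staticmethod
    def _tbv_corr(target: float, seeds=range(5)) -> float:
        """Mean realized cross-harvest TBV correlation over a few seeds.

        Family structure makes a single 2,000-individual draw noisy
        (effective QTL count shrinks toward the number of families), so
        the invariant is asserted on the seed-averaged correlation.
        """
        rs = []
        for s in seeds:
            cfg = _cfg(
                n_progeny=2000, n_markers=2500, n_qtl_sim=2000, n_harvests=2,
                h2_per_harvest=(0.3, 0.3),
                genetic_corr=((1.0, target), (target, 1.0)),
                harvest_means=(0.0, 0.0), n_blocks=1, n_parents=400, seed=s,
            )
            sim = simulate_genotypes(cfg)
            _, truth = simulate_phenotypes(sim, cfg)
            rs.append(truth.true_breeding_values.corr().iloc[0, 1])
        return float(np.mean(rs))

    def test_independent_harvests_give_uncorrelated_tbv(self):
        assert abs(self._tbv_corr(0.0)) < 0.1

    def test_genetic_correlation_recovered(self):
        assert self._tbv_corr(0.6) == pytest.approx(0.6, abs=0.05)

    def test_realized_heritability_near_target(self):
        """With a single block the individual mean is the plot record, so
        var(TBV)/var(phenotype) should sit near the configured 0.25."""
        cfg = _cfg(n_progeny=2000, n_markers=400, n_qtl_sim=200,
                   h2_per_harvest=(0.25,), n_blocks=1, n_parents=40)
        sim = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(sim, cfg)
        means = pheno.groupby("individual")["value"].mean()
        tbv = truth.true_breeding_values["harvest1"].reindex(means.index)
        h2 = tbv.var() / means.var()
        assert h2 == pytest.approx(0.25, abs=0.04)

    def test_heritability_calibrated_over_seeds(self):
        """Mean realized h2 over 20 seeds within +-0.03 per harvest."""
        targets = (0.2, 0.3)
        realized = np.zeros((20, 2))
        for s in range(20):
            cfg = _cfg(
                n_progeny=1000, n_markers=300, n_qtl_sim=200, n_harvests=2,
                h2_per_harvest=targets, genetic_corr=((1.0, 0.5), (0.5, 1.0)),
                harvest_means=(0.0, 0.0), n_blocks=1, n_parents=30, seed=s,
            )
            sim = simulate_genotypes(cfg)
            pheno, truth = simulate_phenotypes(sim, cfg)
            for h in (1, 2):
                means = pheno[pheno["harvest"] == h].groupby("individual")["value"].mean()
                tbv = truth.true_breeding_values[f"harvest{h}"].reindex(means.index)
                realized[s, h - 1] = tbv.var() / means.var()
        for j, target in enumerate(targets):
            assert realized[:, j].mean() == pytest.approx(target, abs=0.03)

    def test_rejects_non_psd_correlation(self):
        with pytest.raises(ValueError, match="semi-definite"):
            _cfg(n_harvests=2, h2_per_harvest=(0.3, 0.3),
                 genetic_corr=((1.0, 2.0), (2.0, 1.0)), harvest_means=(0.0, 0.0))

    def test_rejects_bad_heritability(self):
        with pytest.raises(ValueError, match="heritabilities"):
            _cfg(h2_per_harvest=(0.0,))
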