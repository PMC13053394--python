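"""Synthetic-data generator: determinism, Mendelian consistency, LD decay,
variance calibration."""
import numpy as np
import pytest

from sspleio.datatypes import UNKNOWN_PARENT
from sspleio.simulate import (
    QtlSpec,
    SimulationConfig,
    TraitSpec,
    make_snp_map,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestPedigreeSim:
    def test_founders_only(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=4, n_generations=0))
        assert len(ped) == 4 and ped.n_founders == 4

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_founders=4, n_generations=2, offspring_per_mating=2, seed=1)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert a.ids == b.ids
        assert (a.sire == b.sire).all() and (a.dam == b.dam).all()

    def test_no_animal_is_own_ancestor(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=20, n_generations=4, seed=2))
        for i in range(len(ped)):
            seen = set()
            stack = [i]
            while stack:
                j = stack.pop()
                for p in (ped.sire[j], ped.dam[j]):
                    if p != UNKNOWN_PARENT:
                        assert p != i, "animal is its own ancestor"
                        if p not in seen:
                            seen.add(p)
                            stack.append(p)

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError, match="n_founders"):
            SimulationConfig(n_founders=1)

    def test_generations_do_not_overlap(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=10, n_generations=3, seed=4))
        gen = [i.split("_")[0] for i in ped.ids]
        for i in range(len(ped)):
            if ped.sire[i] != UNKNOWN_PARENT:
                assert int(gen[i][1:]) == int(gen[ped.sire[i]][1:]) + 1


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_founders=60, n_generations=2, n_snps=400,
                           n_chromosomes=2, seed=8)
    ped = simulate_pedigree(cfg)
    geno, haplo = simulate_genotypes(ped, cfg)
    return cfg, ped, geno, haplo


class TestGenotypeSim:
    def test_seed_determinism(self, sim):
        cfg, ped, geno, _ = sim
        geno2, _ = simulate_genotypes(ped, cfg)
        np.testing.assert_array_equal(geno.matrix, geno2.matrix)

    def test_mendelian_consistency(self, sim):
        _, ped, _, haplo = sim
        for i in range(len(ped)):
            for h, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent == UNKNOWN_PARENT:
                    continue
                child = haplo[i, h]
                ok = (child == haplo[parent, 0]) | (child == haplo[parent, 1])
                assert ok.all(), "gamete allele absent from parent"

    def test_maf_within_sampling_error(self, sim):
        cfg, ped, geno, _ = sim
        founders = geno.matrix[: cfg.n_founders]
        p = founders.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        # configured range [0.05, 0.5]; binomial noise at 2N=120 draws
        assert maf.mean() == pytest.approx(0.275, abs=0.05)

    def test_full_sibs_share_more_than_unrelated(self):
        cfg = SimulationConfig(n_founders=100, n_generations=1, offspring_per_mating=4,
                               n_snps=300, n_chromosomes=3, seed=12)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        rng = np.random.default_rng(0)
        sib_ibs, unrel_ibs = [], []
        offspring = [i for i in range(len(ped)) if ped.sire[i] != UNKNOWN_PARENT]
        for _ in range(220):
            i = int(rng.choice(offspring))
            sibs = [j for j in offspring if j != i and ped.sire[j] == ped.sire[i]
                    and ped.dam[j] == ped.dam[i]]
            other = [j for j in offspring if ped.sire[j] != ped.sire[i]
                     and ped.dam[j] != ped.dam[i]]
            if not sibs or not other:
                continue
            j, k = int(rng.choice(sibs)), int(rng.choice(other))
            sib_ibs.append(2 - np.abs(geno.matrix[i] - geno.matrix[j]).mean())
            unrel_ibs.append(2 - np.abs(geno.matrix[i] - geno.matrix[k]).mean())
        assert np.mean(sib_ibs) > np.mean(unrel_ibs)

    def test_r2_decays_with_distance(self):
        cfg = SimulationConfig(n_founders=200, n_generations=0, n_snps=400,
                               n_chromosomes=1, ld_decay_rate=2e-7,
                               n_ancestral_haplotypes=10, seed=13)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        pos = geno.snp_map["position_bp"].to_numpy()
        m = geno.matrix - geno.matrix.mean(axis=0)
        sd = m.std(axis=0)
        keep = sd > 0
        m, pos, sd = m[:, keep], pos[keep], sd[keep]
        corr = (m.T @ m) / len(m) / np.outer(sd, sd)
        iu = np.triu_indices(len(pos), k=1)
        dist = np.abs(pos[iu[0]] - pos[iu[1]])
        r2 = corr[iu] ** 2
        bins = [0, 2e6, 1e7, 5e7, 2e8]
        means = [r2[(dist >= lo) & (dist < hi)].mean() for lo, hi in zip(bins, bins[1:])]
        assert all(a > b for a, b in zip(means, means[1:])), means

    def test_high_decay_rate_gives_independence(self):
        cfg = SimulationConfig(n_founders=300, n_generations=0, n_snps=100,
                               n_chromosomes=1, ld_decay_rate=1.0, seed=14)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        m = geno.matrix
        keep = m.std(axis=0) > 0
        corr = np.corrcoef(m[:, keep], rowvar=False)
        adj = np.diag(corr, k=1)
        assert np.abs(adj).mean() < 3.0 / np.sqrt(cfg.n_founders)

    def test_snp_map_sorted_within_chromosome(self):
        cfg = SimulationConfig(n_snps=200, n_chromosomes=4, seed=3)
        smap = make_snp_map(cfg)
        for _, grp in smap.groupby("chromosome"):
            assert grp["position_bp"].is_monotonic_increasing
            assert grp["position_bp"].is_unique


class TestPhenotypeSim:
    def test_repeatability_recovered(self):
        cfg = SimulationConfig(
            n_founders=2000, n_generations=0, n_snps=10, n_chromosomes=1, seed=21,
            traits=(TraitSpec("MWT", var_additive=1.0, var_pe=0.5, var_residual=1.0),),
            records_per_animal_range=(2, 4), n_cg=1, cg_sd=0.0, parity_sd=0.0,
            age_slope_sd=0.0,
        )
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        records, truth = simulate_phenotypes(ped, geno, cfg)
        # repeatability = corr of two records of the same animal
        wide = records.pivot_table(index="animal", columns=records.groupby("animal").cumcount(), values="value")
        two = wide[[0, 1]].dropna()
        rep = np.corrcoef(two[0], two[1])[0, 1]
        assert rep == pytest.approx(1.5 / 2.5, abs=0.05)

    def test_variance_calibration(self):
        cfg = SimulationConfig(
            n_founders=2000, n_generations=0, n_snps=10, n_chromosomes=1, seed=22,
            traits=(TraitSpec("MWT", var_additive=0.4, var_pe=0.2, var_residual=0.4),),
        )
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, geno, cfg)
        v = truth.tbv.var(ddof=1)
        se = 0.4 * np.sqrt(2 / (2000 - 1))  # var of a variance estimate
        assert abs(v - 0.4) < 3 * se

    def test_null_genetics_gives_no_heritability(self):
        cfg = SimulationConfig(
            n_founders=400, n_generations=0, n_snps=10, n_chromosomes=1, seed=23,
            traits=(TraitSpec("MWT", var_additive=1e-8, var_pe=1e-8, var_residual=1.0),),
        )
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, geno, cfg)
        assert truth.tbv.var() < 1e-6

    def test_pleiotropic_qtl_correlates_traits(self):
        cfg = SimulationConfig(
            n_founders=600, n_generations=0, n_snps=50, n_chromosomes=1, seed=24,
            traits=tuple(TraitSpec(t, 0.1, 0.1, 0.5) for t in ("BCS", "MWT", "MHT")),
            qtl=(QtlSpec(10, (0.5, 0.5, 0.5)), QtlSpec(30, (0.4, 0.4, 0.4))),
        )
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, geno, cfg)
        c = np.corrcoef(truth.tbv, rowvar=False)
        assert (c[np.triu_indices(3, 1)] > 0.3).all()

    def test_repeated_records_share_animal_effects(self):
        cfg = SimulationConfig(n_founders=10, n_generations=0, seed=25,
                               records_per_animal_range=(2, 2), n_snps=10, n_chromosomes=1)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        records, truth = simulate_phenotypes(ped, geno, cfg)
        counts = records.groupby(["animal", "trait"]).size()
        assert (counts == 2).all()

    def test_missing_trait_fraction(self):
        cfg = SimulationConfig(n_founders=400, n_generations=0, seed=26, n_snps=10,
                               n_chromosomes=1, missing_trait_fraction={"MHT": 0.5})
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        records, _ = simulate_phenotypes(ped, geno, cfg)
        n = records.groupby("trait").size()
        assert n["MHT"] < 0.6 * n["MWT"]

    def test_qtl_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SimulationConfig(n_snps=10, qtl=(QtlSpec(10, (0.1, 0.1, 0.1)),))


def test_dataset_bundle_consistency():
    cfg = SimulationConfig(n_founders=30, n_generations=1, n_snps=100, n_chromosomes=2,
                           seed=30, prop_genotyped=0.5)
    ped, geno, geno_all, records, truth = simulate_dataset(cfg)
    assert geno.n_animals == ped.genotyped.sum()
    assert set(geno.animal_ids) <= set(ped.ids)
    assert geno_all.n_animals == len(ped)
    assert set(records["animal"]) <= set(ped.ids)
    # genotyped subset rows agree with the full matrix
    rows = ped.index_of(geno.animal_ids)
    np.testing.assert_array_equal(geno.matrix, geno_all.matrix[rows])
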