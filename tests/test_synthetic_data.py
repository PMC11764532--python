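import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wolfpop.genotype_io import read_plink_text
from wolfpop.popgen_stats import heterozygosity, pairwise_fst
from wolfpop.synthetic_data import (
    ConfigError,
    SimConfig,
    kinship,
    pedigree_inbreeding,
    realized_ne_table,
    simulate_breed,
    simulate_parental_pools,
    two_breed_scenario,
    write_simulation,
)


def small_config(**kw):
    defaults = dict(
        n_chromosomes=4,
        n_snps_per_chromosome=300,
        parental_split_generations=20,
        parental_sizes=(40, 40),
        founder_cross=(2, 2),
        breed_size_per_generation=(20,) * 8,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_invalid_fields_listed(self):
        with pytest.raises(ConfigError, match="missing_rate"):
            SimConfig(missing_rate=1.5)

    def test_infusion_outside_history_rejected(self):
        with pytest.raises(ConfigError, match="infusion_schedule"):
            small_config(infusion_schedule=((99, 1),))


class TestParentalPools:
    def test_no_split_identical_frequencies(self):
        cfg = small_config(parental_split_generations=0)
        dog, wolf, _ = simulate_parental_pools(cfg)
        # founding draws differ but the generating frequencies coincide:
        # with zero drift generations the pool means agree within binomial
        # sampling error on average
        fd = dog.genotypes.mean(0) / 2
        fw = wolf.genotypes.mean(0) / 2
        assert abs((fd - fw).mean()) < 0.01

    def test_determinism_bit_identical(self):
        cfg = small_config(seed=123)
        d1, w1, _ = simulate_parental_pools(cfg)
        d2, w2, _ = simulate_parental_pools(cfg)
        np.testing.assert_array_equal(d1.genotypes, d2.genotypes)
        np.testing.assert_array_equal(w1.genotypes, w2.genotypes)
        pd.testing.assert_frame_equal(d1.snps, d2.snps)

    def test_divergence_matches_drift_expectation(self):
        # mean empirical F_ST across replicates within [0.5x, 1.5x] of
        # 1 - (1 - 1/(2N))^t
        ests, exps = [], []
        for seed in range(4):
            cfg = small_config(seed=seed, parental_split_generations=30)
            dog, wolf, truth = simulate_parental_pools(cfg)
            both = dog.genotypes, wolf.genotypes
            from conftest import make_dataset

            ds = make_dataset(
                np.vstack(both), ["dog"] * dog.n_samples + ["wolf"] * wolf.n_samples,
                chrom=dog.snps["chrom"].tolist(), pos=dog.snps["pos_bp"].tolist(),
            )
            ests.append(pairwise_fst(ds, "dog", "wolf"))
            exps.append(truth.divergence_fst_expected)
        ratio = np.mean(ests) / np.mean(exps)
        assert 0.5 < ratio < 1.5

    def test_allele_frequency_drift_is_unbiased(self):
        # neutral WF: mean frequency change ~ 0 across replicates
        deltas = []
        for seed in range(12):
            cfg = small_config(seed=seed, parental_split_generations=5,
                               n_chromosomes=2, n_snps_per_chromosome=150)
            dog, _, _ = simulate_parental_pools(cfg)
            f0 = 0.5  # symmetric Beta start; compare pool means around it
            deltas.append(float(dog.genotypes.mean() / 2 - f0))
        t = sps.ttest_1samp(deltas, 0.0)
        assert t.pvalue > 0.01


class TestBreed:
    def test_full_sib_offspring_inbreeding(self):
        ped = pd.DataFrame(
            {
                "iid": [1, 2, 3, 4, 5],
                "sire": [None, None, 1, 1, 3],
                "dam": [None, None, 2, 2, 4],
                "sex": [0, 1, 0, 1, 0],
                "generation": [0, 0, 1, 1, 2],
            }
        ).astype({"sire": "Int64", "dam": "Int64"})
        f = pedigree_inbreeding(ped, [3, 5])
        assert f[3] == 0.0
        assert f[5] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "sire,dam,expected",
        [
            # half sibs share one parent -> F = 1/8
            ((1, 2), (1, 3), 0.125),
            # parent-offspring mating -> F = 1/4
            (None, None, 0.25),
        ],
    )
    def test_textbook_pedigree_values(self, sire, dam, expected):
        if sire is None:  # parent x offspring
            ped = pd.DataFrame(
                {"iid": [1, 2, 3, 4], "sire": [None, None, 1, 1],
                 "dam": [None, None, 2, 3], "sex": [0, 1, 1, 0],
                 "generation": [0, 0, 1, 2]}
            ).astype({"sire": "Int64", "dam": "Int64"})
            assert pedigree_inbreeding(ped, [4])[4] == pytest.approx(expected)
        else:
            ped = pd.DataFrame(
                {"iid": [1, 2, 3, 4, 5, 6],
                 "sire": [None, None, None, 1, 1, 4],
                 "dam": [None, None, None, 2, 3, 5],
                 "sex": [0, 1, 1, 0, 1, 0],
                 "generation": [0, 0, 0, 1, 1, 2]}
            ).astype({"sire": "Int64", "dam": "Int64"})
            assert pedigree_inbreeding(ped, [6])[6] == pytest.approx(expected)

    def test_kinship_self_of_founder(self):
        ped = pd.DataFrame(
            {"iid": [1], "sire": [None], "dam": [None], "sex": [0], "generation": [0]}
        ).astype({"sire": "Int64", "dam": "Int64"})
        assert kinship(ped)(1, 1) == pytest.approx(0.5)

    def test_breed_runs_and_records_pedigree(self):
        cfg = small_config(infusion_schedule=((3, 1),))
        dog, wolf, _ = simulate_parental_pools(cfg)
        ds, truth = simulate_breed((dog, wolf), cfg, "bx")
        assert ds.n_samples == cfg.breed_size_per_generation[-1]
        n_founders = sum(cfg.founder_cross) + 1  # + 1 infused wolf
        founders = truth.pedigree["sire"].isna().sum()
        assert founders == n_founders
        assert ((truth.f_ped["f_ped"] >= 0) & (truth.f_ped["f_ped"] < 1)).all()
        ne = truth.realized_ne
        assert set(ne.columns) >= {"generation", "n_sires", "n_dams", "ne_sex_ratio"}
        assert (ne["ne_sex_ratio"] <= 2 * (ne["n_sires"] + ne["n_dams"])).all()

    def test_popular_sire_uniform_limit_matches_multinomial(self):
        # with a huge concentration the sire weights are ~uniform, so
        # offspring counts per sire are multinomial
        counts_var, expect_var = [], []
        for seed in range(15):
            cfg = small_config(seed=seed, popular_sire_weight=1e6,
                               breed_size_per_generation=(40,) * 2,
                               founder_cross=(6, 6), n_chromosomes=1,
                               n_snps_per_chromosome=50,
                               parental_split_generations=1)
            dog, wolf, _ = simulate_parental_pools(cfg)
            _, truth = simulate_breed((dog, wolf), cfg, "bx")
            gen1 = truth.pedigree[truth.pedigree["generation"] == 1]
            per_sire = gen1.groupby("sire").size().reindex(range(1, 7), fill_value=0)
            counts_var.append(per_sire.var(ddof=0))
            n, s = 40, 6
            expect_var.append(n * (1 / s) * (1 - 1 / s))
        assert np.mean(counts_var) == pytest.approx(np.mean(expect_var), rel=0.4)

    def test_heavy_sire_reuse_raises_inbreeding(self):
        f_heavy, f_mild = [], []
        for seed in range(5):
            base = small_config(seed=seed, breed_size_per_generation=(24,) * 10)
            dog, wolf, _ = simulate_parental_pools(base)
            _, t_heavy = simulate_breed(
                (dog, wolf), dataclasses.replace(base, popular_sire_weight=0.1,
                                                 breed_size_per_generation=(24,) * 10), "h")
            _, t_mild = simulate_breed(
                (dog, wolf), dataclasses.replace(base, popular_sire_weight=50.0,
                                                 breed_size_per_generation=(24,) * 10), "m")
            f_heavy.append(t_heavy.f_ped["f_ped"].mean())
            f_mild.append(t_mild.f_ped["f_ped"].mean())
        assert np.mean(f_heavy) > np.mean(f_mild)

    def test_infusion_restores_heterozygosity(self):
        from conftest import make_dataset

        ho_with, ho_without = [], []
        for seed in range(8):
            base = small_config(seed=seed, breed_size_per_generation=(20,) * 8)
            dog, wolf, _ = simulate_parental_pools(base)
            with_inf = dataclasses.replace(base, infusion_schedule=((6, 2),))
            ds_w, _ = simulate_breed((dog, wolf), with_inf, "w")
            ds_n, _ = simulate_breed((dog, wolf), base, "n")
            ho_with.append(heterozygosity(ds_w, "w")[0])
            ho_without.append(heterozygosity(ds_n, "n")[0])
        assert np.mean(ho_with) > np.mean(ho_without)

    def test_phased_parental_input_required(self):
        cfg = small_config()
        dog, wolf, _ = simulate_parental_pools(cfg)
        dog.phased = None
        with pytest.raises(ConfigError):
            simulate_breed((dog, wolf), cfg, "bx")


class TestWriteSimulation:
    def test_round_trip_and_truth_tables(self, tmp_path):
        cfg = small_config(missing_rate=0.02)
        dog, wolf, _ = simulate_parental_pools(cfg)
        ds, truth = simulate_breed((dog, wolf), cfg, "bx")
        write_simulation(ds, truth, tmp_path, config=cfg)
        allele_ref = pd.read_csv(tmp_path / "alleles.tsv", sep="\t", dtype=str)
        back = read_plink_text(tmp_path / "genotypes.ped", tmp_path / "genotypes.map",
                               allele_ref=allele_ref)
        np.testing.assert_array_equal(back.genotypes, ds.genotypes)
        pd.testing.assert_frame_equal(back.snps, ds.snps)
        f_ped = pd.read_csv(tmp_path / "f_ped.tsv", sep="\t")
        assert len(f_ped) == ds.n_samples
        assert "0 0" in (tmp_path / "genotypes.ped").read_text()

    def test_missing_encoded_as_zero_zero(self, tmp_path):
        cfg = small_config(missing_rate=0.1, n_chromosomes=1, n_snps_per_chromosome=60)
        dog, wolf, _ = simulate_parental_pools(cfg)
        ds, truth = simulate_breed((dog, wolf), cfg, "bx")
        write_simulation(ds, truth, tmp_path)
        n_missing = int((ds.genotypes == -1).sum())
        ped_text = (tmp_path / "genotypes.ped").read_text()
        assert sum(line.split().count("0") for line in ped_text.splitlines()) >= n_missing


class TestScenario:
    def test_scenario_shape_and_determinism(self):
        base = small_config()
        ds1, truth1 = two_breed_scenario(seed=5, base=base)
        ds2, _ = two_breed_scenario(seed=5, base=base)
        np.testing.assert_array_equal(ds1.genotypes, ds2.genotypes)
        assert ds1.populations() == ["SAW", "CSW", "GSH", "WLF"]
        counts = ds1.samples["population"].value_counts()
        assert counts["CSW"] == 46 and counts["SAW"] == 20
        assert counts["GSH"] == 12 and counts["WLF"] == 20
        assert truth1["SAW"].f_ped["f_ped"].mean() > 0
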