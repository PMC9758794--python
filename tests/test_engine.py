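"""Coalescent engine: model builders, simulation moments, reproducibility."""

import numpy as np
import pytest

import raddemog as rd
from raddemog import kingman
from raddemog.demography import build_fim, build_ns, build_ss
from raddemog.sfs import diversity_stats
from raddemog.simulate import SimConfig, sim_folded_sfs, sim_genotypes


class TestBuilders:
    def test_ns_time_zero_is_constant_at_ancestral_size(self):
        m = build_ns(5000, 20_000, 0)
        assert m.initial_size("deme0") == 20_000
        assert m.size_changes == []

    def test_fim_rates_and_merge(self):
        m = build_fim(N_deme=500, Nm=2.0, T_col_gen=1000, N_anc=5000, n_demes=4)
        _, _, mat = m.migration_epochs[0]
        assert mat[0, 1] == pytest.approx(2.0 / (500 * 3))
        assert np.all(np.diag(mat) == 0)
        assert m.merges[0][0] == 1000

    def test_fim_two_demes_is_symmetric_island_pair(self):
        m = build_fim(N_deme=500, Nm=1.0, T_col_gen=1000, N_anc=5000, n_demes=2)
        _, _, mat = m.migration_epochs[0]
        assert mat.shape == (2, 2)
        assert mat[0, 1] == mat[1, 0] == pytest.approx(1.0 / 500)

    def test_ss_neighbourhoods(self):
        m = build_ss(N_deme=500, Nm=1.0, T_col_gen=1000, N_anc=5000, grid=(10, 10))
        _, _, mat = m.migration_epochs[0]
        degree = (mat > 0).sum(axis=1)
        corner = 0  # top-left
        interior = 5 * 10 + 5
        assert degree[corner] == 2
        assert degree[interior] == 4
        edge = 5  # top row, not a corner
        assert degree[edge] == 3

    def test_negative_migration_rejected(self):
        with pytest.raises(ValueError):
            build_fim(N_deme=500, Nm=-1, T_col_gen=1000, N_anc=5000)

    def test_dict_round_trip(self):
        m = build_fim(N_deme=500, Nm=1.0, T_col_gen=1000, N_anc=5000, n_demes=3)
        back = rd.DemographyModel.from_dict(m.to_dict())
        assert back.populations == m.populations
        assert np.array_equal(back.migration_epochs[0][2], m.migration_epochs[0][2])


class TestSimulate:
    def test_seed_reproducibility_bit_for_bit(self):
        model = build_ns(8000, 8000, 0)
        cfg = SimConfig(samples={"deme0": 4}, n_loci=300, seed=42)
        a = sim_genotypes(model, cfg)
        b = sim_genotypes(model, cfg)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.pos_in_locus.tolist() == b.pos_in_locus.tolist()
        c = sim_genotypes(model, SimConfig(samples={"deme0": 4}, n_loci=300, seed=43))
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_zero_mutation_rate_gives_no_snps(self):
        model = build_ns(8000, 8000, 0)
        data = sim_genotypes(model, SimConfig(samples={"deme0": 4}, n_loci=50, mu=0.0, seed=1))
        assert data.n_sites == 0

    def test_oversampling_a_deme_errors(self):
        model = build_ns(5, 5, 0)
        with pytest.raises(ValueError):
            sim_genotypes(model, SimConfig(samples={"deme0": 6}, n_loci=10, seed=1))

    def test_watterson_expectation(self):
        # E[S] = 4 N mu a1 L within 3 SE
        N, n_hap, n_loci = 10_000, 10, 4000
        model = build_ns(N, N, 0)
        sfs = sim_folded_sfs(model, SimConfig(samples={"deme0": 5}, n_loci=n_loci, seed=9), "deme0")
        a1 = sum(1 / i for i in range(1, n_hap))
        expected = 4 * N * 1.93e-8 * a1 * n_loci * 125
        # var(S) per locus ~ theta*a1 + theta^2*a2 (Watterson); bound loosely by 3x Poisson SE
        se = 3 * np.sqrt(2 * expected)
        assert abs(sfs.S - expected) < se

    def test_divergence_limit_fst_near_one(self):
        spec = rd.IMModelSpec("div")
        params = {
            "N_anc": 5000, "N_mod_IP": 5000, "N_mod_AO": 5000,
            "N_anc_IP": 5000, "N_anc_AO": 5000,
            "T_s_IP": 1000, "T_s_AO": 1000, "T_div": 900_000,
        }
        model = rd.build_im_demography(spec, params)
        cfg = SimConfig(samples={"IP": 4, "AO": 4}, n_loci=1500, seed=13)
        data = sim_genotypes(model, cfg)
        ip = [s for s, l in zip(data.samples, data.site_labels) if l == "IP"]
        ao = [s for s, l in zip(data.samples, data.site_labels) if l == "AO"]
        res = rd.reynolds_fst(data, ip, ao, min_maf=0.0)
        assert res.fst > 0.85


class TestStructureSignatures:
    def test_low_migration_island_inflates_tajimas_d(self):
        # sampling one deme of a low-Nm metapopulation mimics a bottleneck
        fim = build_fim(N_deme=500, Nm=0.2, T_col_gen=50_000, N_anc=5000)
        cfg = SimConfig(samples={"deme0": 6}, n_loci=500, seed=21)
        sfs = sim_folded_sfs(fim, cfg, "deme0")
        d_struct = diversity_stats(sfs).tajimas_d
        ns = build_ns(500, 500, 0)
        sfs0 = sim_folded_sfs(ns, cfg, "deme0")
        d_panmictic = diversity_stats(sfs0).tajimas_d
        assert d_struct > 0.3
        assert d_struct > d_panmictic

    def test_high_migration_island_approaches_panmixia(self):
        fim = build_fim(N_deme=500, Nm=100.0, T_col_gen=2000, N_anc=20_000)
        cfg = SimConfig(samples={"deme0": 6}, n_loci=150, seed=22)
        d = diversity_stats(sim_folded_sfs(fim, cfg, "deme0")).tajimas_d
        assert abs(d) < 0.5

    def test_stepping_stone_at_least_as_isolated_as_island(self):
        # nearest-neighbour migration mixes more slowly than uniform
        # migration, so the sampled-deme D is larger on average
        d_ss, d_fim = [], []
        for s in range(4):
            cfg = SimConfig(samples={"deme55": 6}, n_loci=300, seed=100 + s)
            ss = build_ss(N_deme=500, Nm=0.5, T_col_gen=50_000, N_anc=5000)
            d_ss.append(diversity_stats(sim_folded_sfs(ss, cfg, "deme55")).tajimas_d)
            cfg0 = SimConfig(samples={"deme0": 6}, n_loci=300, seed=200 + s)
            fim = build_fim(N_deme=500, Nm=0.5, T_col_gen=50_000, N_anc=5000)
            d_fim.append(diversity_stats(sim_folded_sfs(fim, cfg0, "deme0")).tajimas_d)
        assert np.mean(d_ss) >= np.mean(d_fim) - 0.05


class TestKingmanSampler:
    def test_matches_analytic_constant_size(self):
        rng = np.random.default_rng(7)
        ours = kingman.branch_afs(8, 30_000, [(0.0, 5000)], rng).mean(axis=0)
        analytic = 4 * 5000 / np.arange(1, 8)
        assert np.allclose(ours, analytic, rtol=0.03)

    def test_matches_analytic_and_msprime_size_change(self):
        # tight agreement with the exact piecewise expectation; loose
        # agreement with an msprime estimate (2500 replicates carry up
        # to ~15% Monte-Carlo error in the rare classes)
        import msprime

        from raddemog.skyline import expected_branch_lengths

        rng = np.random.default_rng(9)
        epochs = [(0.0, 1000.0), (2000.0, 20_000.0)]
        ours = kingman.branch_afs(8, 30_000, epochs, rng).mean(axis=0)
        assert np.allclose(ours, expected_branch_lengths(8, epochs), rtol=0.04)
        dem = msprime.Demography()
        dem.add_population(name="p", initial_size=1000)
        dem.add_population_parameters_change(time=2000, initial_size=20_000)
        total = np.zeros(7)
        for ts in msprime.sim_ancestry(
            samples={"p": 4}, demography=dem, num_replicates=2500, random_seed=10
        ):
            total += ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=False
            )[1:8]
        assert np.allclose(ours, total / 2500, rtol=0.25)

    def test_mean_tajimas_d_near_zero_under_constant_size(self):
        from raddemog.sfs import _td_from_eta

        rng = np.random.default_rng(11)
        branch = kingman.branch_afs(10, 400 * 150, [(0.0, 10_000)], rng)
        per_rep = branch.reshape(400, 150, 9).sum(axis=1)
        eta = kingman.sample_folded_eta(per_rep, 1.93e-8 * 125, rng)
        td = _td_from_eta(eta, 10)
        td = td[~np.isnan(td)]
        assert abs(td.mean()) < 3 * td.std() / np.sqrt(len(td))

    def test_theta_pi_and_theta_w_agree_in_expectation(self):
        rng = np.random.default_rng(12)
        branch = kingman.branch_afs(10, 400 * 200, [(0.0, 10_000)], rng)
        per_rep = branch.reshape(400, 200, 9).sum(axis=1)
        eta = kingman.sample_folded_eta(per_rep, 1.93e-8 * 125, rng)
        i = np.arange(1, 6)
        n = 10
        pi = (eta * i * (n - i)).sum(axis=1) / 45
        a1 = sum(1 / k for k in range(1, 10))
        tw = eta.sum(axis=1) / a1
        assert pi.mean() / tw.mean() == pytest.approx(1.0, abs=0.05)
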