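import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raddemog.datasets import MISSING
from raddemog.sfs import (
    FoldedSFS,
    Joint2DSFS,
    diversity_stats,
    fold_sfs_from_genotypes,
    joint_sfs_from_genotypes,
    tajima_constants,
    td_significance,
)
from raddemog import kingman
from tests.conftest import make_dataset


class TestFold1D:
    def test_half_count_site_is_self_mirror(self):
        # 3 diploids, one site with genotypes (0,1,2): alternate count 3 = n/2
        data = make_dataset([[0, 1, 2]])
        sfs = fold_sfs_from_genotypes(data, data.samples)
        assert sfs.n_hap == 6
        assert sfs.eta.tolist() == [0, 0, 1]
        assert sfs.n_monomorphic == 0

    def test_fixed_alternate_site_folds_to_monomorphic(self):
        data = make_dataset([[2, 2, 2]])
        sfs = fold_sfs_from_genotypes(data, data.samples)
        assert sfs.n_monomorphic == 1
        assert sfs.S == 0

    def test_ten_sites_enumerated_by_hand(self):
        # alternate counts {1,1,1,2,3,5,5,6,0,0} for n_hap=6
        counts = [1, 1, 1, 2, 3, 5, 5, 6, 0, 0]
        rows = []
        for c in counts:
            g = [0, 0, 0]
            for i in range(3):
                g[i] = min(2, max(0, c - 2 * i))
            rows.append(g)
        # folds: 1,1,1,5,5 -> minor 1; 2 -> 2; 3 -> 3; 6,0,0 -> monomorphic
        data = make_dataset(rows)
        sfs = fold_sfs_from_genotypes(data, data.samples)
        assert sfs.eta.tolist() == [5, 1, 1]
        assert sfs.n_monomorphic == 3
        assert sfs.L == 10

    def test_missing_sites_are_dropped_and_counted(self):
        data = make_dataset([[0, 1, 2], [MISSING, 1, 1], [1, 1, 0]])
        sfs = fold_sfs_from_genotypes(data, data.samples)
        assert sfs.n_dropped == 1
        assert sfs.L == 2

    def test_total_sites_adds_invariant_loci(self):
        data = make_dataset([[0, 1, 2]])
        sfs = fold_sfs_from_genotypes(data, data.samples, total_sites=125)
        assert sfs.n_monomorphic == 124

    def test_errors(self):
        data = make_dataset([[MISSING, 1, 1]])
        with pytest.raises(ValueError):
            fold_sfs_from_genotypes(data, [])
        with pytest.raises(ValueError):
            fold_sfs_from_genotypes(data, data.samples)


class TestFold2D:
    def make_joint(self, pairs):
        # two diploids per group; encode any count 0..4 as two genotypes
        rows = []
        for c1, c2 in pairs:
            enc = lambda c: [min(2, c), max(0, c - 2)]
            rows.append(enc(c1) + enc(c2))
        return make_dataset(rows)

    def test_global_max_folds_to_origin(self):
        data = self.make_joint([(4, 4)])
        sfs = joint_sfs_from_genotypes(data, data.samples[:2], data.samples[2:])
        assert sfs.counts[0, 0] == 1

    def test_minor_entry_stays(self):
        data = self.make_joint([(1, 0)])
        sfs = joint_sfs_from_genotypes(data, data.samples[:2], data.samples[2:])
        assert sfs.counts[1, 0] == 1

    def test_six_sites_enumerated_by_hand(self):
        pairs = [(3, 3), (1, 2), (0, 4), (4, 4), (2, 2), (1, 0)]
        data = self.make_joint(pairs)
        sfs = joint_sfs_from_genotypes(data, data.samples[:2], data.samples[2:])
        expected = {(1, 1): 1, (1, 2): 1, (0, 4): 1, (0, 0): 1, (2, 2): 1, (1, 0): 1}
        for (i, j), v in expected.items():
            assert sfs.counts[i, j] == v, (i, j)
        assert sfs.total == 6

    def test_overlapping_groups_error(self):
        data = self.make_joint([(1, 1)])
        with pytest.raises(ValueError):
            joint_sfs_from_genotypes(data, data.samples[:2], data.samples[1:3])

    def test_tie_cells_not_merged_with_mirror(self):
        counts = np.zeros((5, 5))
        counts[0, 4] = 3
        counts[4, 0] = 2
        folded = Joint2DSFS(4, 4, counts, folded=False).fold()
        assert folded.counts[0, 4] == 3 and folded.counts[4, 0] == 2


class TestDiversity:
    def test_watterson_from_direct_summation(self):
        sfs = FoldedSFS(10, [3, 1, 1, 0, 0], 995)
        a1 = sum(1 / i for i in range(1, 10))
        st_ = diversity_stats(sfs)
        assert st_.theta_w == pytest.approx(5 / (a1 * 1000), rel=1e-12)
        assert st_.theta_w == pytest.approx(1.7674e-3, rel=1e-3)

    def test_pi_from_pairwise_definition(self):
        sfs = FoldedSFS(10, [3, 1, 1, 0, 0], 995)
        st_ = diversity_stats(sfs)
        assert st_.theta_pi == pytest.approx((3 * 9 + 1 * 16 + 1 * 21) / (45 * 1000), rel=1e-12)
        assert st_.theta_pi == pytest.approx(1.4222e-3, rel=1e-3)

    def test_tajimas_d_sign_follows_pi_minus_watterson(self):
        st_ = diversity_stats(FoldedSFS(10, [3, 1, 1, 0, 0], 995))
        assert st_.tajimas_d < 0

    def test_monomorphic_flagged_not_nan(self):
        st_ = diversity_stats(FoldedSFS(10, [0, 0, 0, 0, 0], 100))
        assert st_.theta_pi == 0 and st_.theta_w == 0
        assert st_.tajimas_d is None

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            diversity_stats(FoldedSFS(2, [1], 10))

    def test_pi_equals_bruteforce_all_pairs(self):
        """SFS-based pi must equal explicit all-pairs haplotype comparison."""
        import msprime

        ts = msprime.sim_ancestry(
            samples=5, population_size=10_000, sequence_length=5000,
            discrete_genome=False, random_seed=5,
        )
        mts = msprime.sim_mutations(
            ts, rate=1e-7, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=6,
        )
        H = mts.genotype_matrix().T  # haplotypes x sites
        n = H.shape[0]
        brute = sum(
            np.sum(H[a] != H[b]) for a in range(n) for b in range(a + 1, n)
        ) / math.comb(n, 2)
        c = H.sum(axis=0)
        eta = np.bincount(np.minimum(c, n - c), minlength=n // 2 + 1)[1:]
        sfs = FoldedSFS(n, eta.astype(float), 0)
        st_ = diversity_stats(sfs)
        assert st_.theta_pi * sfs.L == pytest.approx(brute, rel=1e-12)


class TestRoundTrips:
    def test_fsc_1d(self, tmp_path):
        sfs = FoldedSFS(10, [5, 4, 3, 2, 1], 985)
        path = str(tmp_path / "sfs.obs")
        sfs.to_fsc(path)
        back = FoldedSFS.from_fsc(path)
        assert back.n_hap == 10
        assert back.eta.tolist() == sfs.eta.tolist()
        assert back.n_monomorphic == 985

    def test_fsc_2d(self, tmp_path):
        counts = np.arange(15, dtype=float).reshape(5, 3)
        sfs = Joint2DSFS(4, 2, counts, folded=True)
        path = str(tmp_path / "joint.obs")
        sfs.to_fsc(path)
        back = Joint2DSFS.from_fsc(path)
        assert back.n1_hap == 4 and back.n2_hap == 2
        assert np.array_equal(back.counts, counts)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
    def test_fold_conserves_sites(self, xi):
        eta = kingman.fold_xi(np.array(xi, dtype=float))[0]
        assert eta.sum() == sum(xi)
        n = 10
        for i in range(1, n // 2):
            assert eta[i - 1] == xi[i - 1] + xi[n - i - 1]
        assert eta[n // 2 - 1] == xi[n // 2 - 1]


class TestTDSignificance:
    def test_neutral_sfs_not_rejected(self):
        # eta proportional to the constant-size expectation: D ~ 0, p large
        n = 10
        exp = np.array([1 / i + 1 / (n - i) for i in range(1, 5)] + [1 / 5])
        eta = np.round(exp / exp.sum() * 2000)
        sfs = FoldedSFS(n, eta, 100_000 - int(eta.sum()))
        p = td_significance(sfs, n_sims=400, seed=1)
        assert p > 0.5

    def test_expansion_rejected(self):
        # 100-fold expansion: excess singletons, strongly negative D
        rng = np.random.default_rng(2)
        branch = kingman.branch_afs(10, 2500, [(0.0, 20_000), (2000.0, 200.0)], rng)
        eta = kingman.fold_xi(rng.poisson(branch.sum(axis=0) * 1.93e-8 * 125))[0]
        sfs = FoldedSFS(10, eta, 2500 * 125 - int(eta.sum()))
        assert diversity_stats(sfs).tajimas_d < 0
        p = td_significance(sfs, n_sims=1000, seed=3)
        assert p <= 0.001

    def test_small_sims_warns(self):
        sfs = FoldedSFS(6, [30, 20, 10], 5000)
        with pytest.warns(UserWarning):
            td_significance(sfs, n_sims=50, seed=1)

    def test_conditioning_on_s_supported(self):
        sfs = FoldedSFS(6, [30, 20, 10], 5000)
        p = td_significance(sfs, n_sims=150, seed=4, condition="S")
        assert 0 <= p <= 1


def test_tajima_constants_published_values():
    # a1 for n=10 and the b1 identity, straight from the definitions
    c = tajima_constants(10)
    assert c["a1"] == pytest.approx(2.828968, abs=1e-6)
    assert c["b1"] == pytest.approx(11 / 27)
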