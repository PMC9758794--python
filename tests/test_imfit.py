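import numpy as np
import pytest

import raddemog as rd
from raddemog.imfit import (
    IMModelSpec,
    build_im_demography,
    composite_loglik,
    distinguishability_check,
    expected_2dsfs,
    fit_model,
    parametric_bootstrap,
    saturated_loglik,
    select_model,
)
from raddemog.simulate import SimConfig, sim_joint_sfs


def sym_params(tdiv=100_000, nm=1.0, variant="bsc"):
    p = {
        "N_anc": 5000, "N_mod_IP": 5000, "N_mod_AO": 5000,
        "N_anc_IP": 5000, "N_anc_AO": 5000,
        "T_s_IP": 1000, "T_s_AO": 1000, "T_div": tdiv,
    }
    if variant == "bsc":
        p.update(Nm_IP_AO=nm, Nm_AO_IP=nm)
    return p


class TestModelSpecs:
    @pytest.mark.parametrize(
        "variant,k", [("full", 13), ("anc", 11), ("rec", 11), ("bsc", 10), ("div", 8)]
    )
    def test_free_parameter_counts(self, variant, k):
        assert IMModelSpec(variant).k == k

    def test_div_refuses_migration(self):
        spec = IMModelSpec("div")
        with pytest.raises(ValueError, match="migration"):
            spec.validate({**sym_params(variant="div"), "Nm_IP_AO": 1.0})

    def test_tmig_after_tdiv_rejected(self):
        spec = IMModelSpec("full")
        p = sym_params(variant="div")
        p.update(T_mig=200_000, Nm1_IP_AO=1, Nm1_AO_IP=1, Nm2_IP_AO=1, Nm2_AO_IP=1)
        with pytest.raises(ValueError, match="T_mig"):
            build_im_demography(spec, p)

    def test_div_demography_has_no_migration(self):
        model = build_im_demography(IMModelSpec("div"), sym_params(variant="div"))
        assert model.migration_epochs == []

    def test_bsc_single_constant_epoch(self):
        model = build_im_demography(IMModelSpec("bsc"), sym_params(tdiv=100_000, nm=2.0))
        assert len(model.migration_epochs) == 1
        t0, t1, m = model.migration_epochs[0]
        assert t0 == 0 and t1 == pytest.approx(10_000)  # years -> generations
        assert m[0, 1] == pytest.approx(2.0 / 5000)
        assert m[1, 0] == pytest.approx(2.0 / 5000)

    def test_full_two_epoch_structure(self):
        spec = IMModelSpec("full")
        p = sym_params(variant="div")
        p.update(T_mig=20_000, Nm1_IP_AO=3, Nm1_AO_IP=0.5, Nm2_IP_AO=1, Nm2_AO_IP=1)
        model = build_im_demography(spec, p)
        assert len(model.migration_epochs) == 2
        (a0, a1, ma), (b0, b1, mb) = model.migration_epochs
        assert (a0, a1) == (0, 2000)
        assert (b0, b1) == (2000, pytest.approx(10_000))
        assert ma[0, 1] == pytest.approx(3 / 5000)
        assert mb[0, 1] == pytest.approx(1 / 5000)


class TestCompositeLikelihood:
    def test_direct_arithmetic(self):
        lnl = composite_loglik(np.array([30.0, 20, 50]), np.array([0.3, 0.2, 0.5]), min_entry=1)
        assert lnl == pytest.approx(30 * np.log(0.3) + 20 * np.log(0.2) + 50 * np.log(0.5))

    def test_pooling_of_small_entries(self):
        m = np.array([30.0, 20, 5, 4])
        p = np.array([0.4, 0.3, 0.2, 0.1])
        lnl = composite_loglik(m, p, min_entry=10)
        # classes {30, 20, 9} with probabilities {0.4, 0.3, 0.3}
        expected = 30 * np.log(0.4) + 20 * np.log(0.3) + 9 * np.log(0.3)
        assert lnl == pytest.approx(expected)

    def test_saturated_is_maximum(self):
        m = np.array([30.0, 20, 50])
        sat = saturated_loglik(m, np.ones(3), min_entry=1)
        assert sat == pytest.approx(composite_loglik(m, m / m.sum(), min_entry=1))
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            assert composite_loglik(m, p, min_entry=1) <= sat + 1e-9

    def test_all_pooled_errors(self):
        with pytest.raises(ValueError):
            composite_loglik(np.array([1.0, 2.0]), np.array([0.5, 0.5]), min_entry=10)

    def test_aic_arithmetic(self):
        # k = 10 free parameters at lnL = -102.965
        assert 2 * 10 - 2 * (-102.965) == pytest.approx(225.93)


class TestExpectedSFS:
    def test_probabilities_and_masking(self):
        spec = IMModelSpec("bsc")
        P = expected_2dsfs(spec, sym_params(), n_sims=2000, seed=1, samples=(3, 3))
        assert P.shape == (7, 7)
        assert P.sum() == pytest.approx(1.0)
        # monomorphic class dominates per-site probability; tie cells excluded
        assert P[0, 0] > 0.9
        assert P[6, 0] == 0 and P[0, 6] == 0
        i, j = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
        assert P[(i + j) > 6].sum() == 0  # folded

    @staticmethod
    def poly_probs(P):
        Q = P.copy()
        Q[0, 0] = 0
        return Q / Q.sum()

    def test_symmetric_model_symmetric_spectrum(self):
        spec = IMModelSpec("bsc")
        P = expected_2dsfs(spec, sym_params(), n_sims=20_000, seed=2, samples=(3, 3))
        Q = self.poly_probs(P)
        off = np.abs(Q - Q.T)[Q + Q.T > 0.01]
        assert off.max() < 0.012

    def test_isolation_concentrates_on_private_cells(self):
        spec = IMModelSpec("div")
        P = expected_2dsfs(
            spec, sym_params(tdiv=2_000_000, variant="div"), n_sims=4000, seed=3,
            samples=(3, 3),
        )
        Q = self.poly_probs(P)
        private = Q[1:, 0].sum() + Q[0, 1:].sum()
        assert private > 0.8

    def test_monte_carlo_error_scaling(self):
        spec = IMModelSpec("bsc")
        cells = [(1, 0), (0, 1), (1, 1)]
        ses = []
        for n_sims in (1000, 4000):
            vals = np.array(
                [
                    [
                        expected_2dsfs(spec, sym_params(), n_sims=n_sims, seed=100 + r,
                                       samples=(3, 3))[c]
                        for c in cells
                    ]
                    for r in range(5)
                ]
            )
            ses.append(vals.std(axis=0))
        ratio = ses[0] / ses[1]
        assert np.median(ratio) == pytest.approx(2.0, abs=1.1)

    def test_min_sims_enforced(self):
        with pytest.raises(ValueError):
            expected_2dsfs(IMModelSpec("bsc"), sym_params(), n_sims=10, seed=1)


@pytest.fixture(scope="module")
def toy_obs():
    """2D-SFS simulated under a known 2-parameter truth (div variant)."""
    spec = IMModelSpec("div")
    truth = sym_params(tdiv=150_000, variant="div")
    truth["N_anc"] = 3000
    model = build_im_demography(spec, truth)
    cfg = SimConfig(samples={"IP": 3, "AO": 3}, n_loci=15_000, seed=77)
    return spec, truth, sim_joint_sfs(model, cfg, ("IP", "AO"))


class TestFitting:
    def test_two_parameter_recovery(self, toy_obs):
        spec, truth, obs = toy_obs
        fixed = {k: v for k, v in truth.items() if k not in ("N_anc", "T_div")}
        fit = fit_model(
            spec, obs, n_runs=2, n_sims=1500, maxiter=15, seed=5,
            fixed_params=fixed,
        )
        assert abs(fit.ml_params["N_anc"] - truth["N_anc"]) / truth["N_anc"] < 0.25
        assert abs(fit.ml_params["T_div"] - truth["T_div"]) / truth["T_div"] < 0.25
        assert fit.n_free == 2
        assert fit.lnl_composite <= fit.lnl_saturated
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.lnl_composite)

    def test_more_runs_never_worse(self, toy_obs):
        # best-of-more-restarts is weakly better, up to the Monte-Carlo
        # noise of the final re-evaluation (a few lnL units here)
        spec, truth, obs = toy_obs
        fixed = {k: v for k, v in truth.items() if k not in ("N_anc", "T_div")}
        f1 = fit_model(spec, obs, n_runs=1, n_sims=1200, maxiter=8, seed=9,
                       fixed_params=fixed, structured_starts=False)
        f6 = fit_model(spec, obs, n_runs=6, n_sims=1200, maxiter=8, seed=9,
                       fixed_params=fixed, structured_starts=False)
        # non-nested Latin-hypercube start sets: allow re-scoring noise
        assert f6.lnl_composite >= f1.lnl_composite - 15.0

    def test_refit_self_consistency(self, toy_obs):
        spec, truth, obs = toy_obs
        # scoring the expected SFS generated at the truth twice differs only
        # by Monte-Carlo noise
        a = composite_loglik(obs, expected_2dsfs(spec, truth, 4000, seed=1, samples=(3, 3)))
        b = composite_loglik(obs, expected_2dsfs(spec, truth, 4000, seed=2, samples=(3, 3)))
        assert abs(a - b) < 30

    def test_select_model_rank_and_pooling_guard(self, toy_obs):
        spec, truth, obs = toy_obs
        fixed = {k: v for k, v in truth.items() if k not in ("N_anc",)}
        fit1 = fit_model(spec, obs, n_runs=1, n_sims=1200, maxiter=6, seed=3,
                         fixed_params=fixed, structured_starts=False)
        fit2 = fit_model(spec, obs, n_runs=1, n_sims=1200, maxiter=6, seed=4,
                         fixed_params=fixed, min_entry=5, structured_starts=False)
        with pytest.raises(ValueError):
            select_model([fit1, fit2])
        fit3 = fit_model(spec, obs, n_runs=1, n_sims=1200, maxiter=6, seed=5,
                         fixed_params=fixed, structured_starts=False)
        ranking = select_model([fit1, fit3])
        assert ranking[0]["delta_aic"] == 0
        assert ranking[0]["aic"] <= ranking[1]["aic"]

    def test_bootstrap_input_validation(self, toy_obs):
        spec, truth, obs = toy_obs
        with pytest.raises(ValueError):
            parametric_bootstrap(
                spec, truth, SimConfig(samples={"IP": 3, "AO": 3}, n_loci=100), n_boot=0
            )


class TestDistinguishability:
    def test_identical_specs_overlap_and_order_invariance(self, toy_obs):
        spec, truth, obs = toy_obs
        f = lambda: type("F", (), {})  # noqa: E731
        from raddemog.imfit import FitResult

        fit = FitResult(
            spec=spec, ml_params=truth, lnl_composite=0, lnl_saturated=0, aic=0,
            n_runs=1, run_lnls=[0], seed=1, min_entry=10, n_free=8, improved=True,
        )
        fit2 = FitResult(
            spec=IMModelSpec("bsc"), ml_params={**truth, "Nm_IP_AO": 0.001, "Nm_AO_IP": 0.001},
            lnl_composite=0, lnl_saturated=0, aic=0, n_runs=1, run_lnls=[0], seed=1,
            min_entry=10, n_free=10, improved=True,
        )
        out = distinguishability_check([fit, fit2], obs, n_rep=10, n_sims=1500, seed=6)
        # near-identical models: overlapping likelihood distributions
        assert list(out["verdicts"].values())[0] == "not distinguishable"
        out_rev = distinguishability_check([fit2, fit], obs, n_rep=10, n_sims=1500, seed=6)
        assert out["verdicts"] == out_rev["verdicts"]
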