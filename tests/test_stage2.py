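import numpy as np
import pandas as pd
import pytest

from eratrend import stage2 as s2
from eratrend.errors import ConnectivityError, ConvergenceError, SchemaError
from eratrend.stage1 import Stage1Result
from eratrend.stage2 import (
    FA2Fit,
    GxETable,
    build_gxe_table,
    fit_stage2_fa2,
    genetic_correlation_matrix,
    pairwise_connectivity,
)
from eratrend.synthetic_data import simulate_gxe_table


def _result(trial, genos, values, se=0.2):
    return Stage1Result(
        trial=trial,
        blues=pd.DataFrame({"genotype": genos, "blue": values, "se": se}),
        varcomp={"residual": 0.1}, h2_cullis=0.7, h2_piepho=0.7, reliability=0.6,
        trial_mean=float(np.mean(values)), covariate_coefs={}, n_obs=3 * len(genos),
    )


def _table(blues, ses=None):
    if ses is None:
        ses = blues.where(blues.isna(), 0.2)
    return GxETable(blues, ses)


def _fa2fit(loadings, psi, trials):
    lam = pd.DataFrame(loadings, index=trials,
                       columns=[f"factor{i+1}" for i in range(np.shape(loadings)[1])])
    psi = pd.Series(psi, index=trials)
    G = lam.to_numpy() @ lam.to_numpy().T + np.diag(psi)
    return FA2Fit(
        loadings=lam, psi=psi, sigma2_g=0.0, sigma2_theta=1.0, mu=4.0,
        env_effects=pd.Series(0.0, index=trials),
        breeding_values=pd.DataFrame({"genotype": [], "value": [], "se": []}),
        G_env=pd.DataFrame(G, index=trials, columns=trials),
        used_nrm=False, nrm_fallback=False, n_factors=lam.shape[1],
        converged=True, loglik=0.0,
    )


class TestBuildTable:
    def test_shared_genotypes_complete_table(self):
        genos = list("ABCDE")
        res = [_result("T1", genos, np.arange(5.0)), _result("T2", genos, np.arange(5.0) + 1)]
        table = build_gxe_table(res)
        assert table.blues.shape == (5, 2)
        assert table.mask.all().all()

    def test_partial_overlap_creates_missing_cells(self):
        res = [_result("T1", ["A", "B", "C"], [1.0, 2.0, 3.0]),
               _result("T2", ["B", "C", "D"], [2.0, 3.0, 4.0])]
        table = build_gxe_table(res)
        assert table.blues.shape == (4, 2)
        assert int((~table.mask).sum().sum()) == 2

    def test_duplicate_genotype_rejected(self):
        res = [_result("T1", ["A", "A", "B"], [1.0, 1.1, 2.0])]
        with pytest.raises(SchemaError, match="duplicate"):
            build_gxe_table(res)

    def test_round_trip_preserves_values_and_mask(self, tmp_path):
        res = [_result("T1", ["A", "B", "C"], [1.0, 2.0, 3.0]),
               _result("T2", ["B", "C", "D"], [2.0, 3.0, 4.0])]
        table = build_gxe_table(res)
        path = tmp_path / "gxe.csv"
        table.to_csv(path)
        back = GxETable.from_csv(path)
        pd.testing.assert_frame_equal(back.blues, table.blues)
        pd.testing.assert_frame_equal(back.ses, table.ses)

    def test_nonpositive_se_rejected(self):
        blues = pd.DataFrame({"T1": [1.0, 2.0], "T2": [2.0, 1.0]}, index=["A", "B"])
        ses = blues.where(blues.isna(), 0.0)
        with pytest.raises(SchemaError, match="SE"):
            GxETable(blues, ses)


class TestConnectivity:
    def test_identical_sets(self):
        genos = list("ABCD")
        table = build_gxe_table([_result("T1", genos, np.ones(4)),
                                 _result("T2", genos, np.ones(4))])
        conn = pairwise_connectivity(table)
        assert conn.loc["T1", "T2"] == 4
        assert conn.loc["T1", "T1"] == 4

    def test_partial_and_disjoint_overlap(self):
        res = [_result("T1", ["A", "B", "C"], np.ones(3)),
               _result("T2", ["B", "C", "D"], np.ones(3)),
               _result("T3", ["E", "F"], np.ones(2))]
        conn = pairwise_connectivity(build_gxe_table(res))
        assert conn.loc["T1", "T2"] == 2
        assert conn.loc["T1", "T3"] == 0

    def test_disconnected_table_raises_with_components(self):
        res = [_result("T1", ["A", "B"], np.ones(2)),
               _result("T2", ["C", "D"], np.ones(2))]
        table = build_gxe_table(res)
        with pytest.raises(ConnectivityError) as err:
            fit_stage2_fa2(table)
        assert len(err.value.components) == 2


class TestGeneticCorrelations:
    def test_hand_computed_half(self):
        fit = _fa2fit([[1.0, 0.0], [1.0, 0.0]], [1.0, 1.0], ["E1", "E2"])
        corr = genetic_correlation_matrix(fit)
        assert corr.loc["E1", "E2"] == pytest.approx(0.5)
        assert corr.loc["E1", "E1"] == 1.0

    def test_rank_one_limit_gives_unit_correlations(self):
        fit = _fa2fit([[0.5, 0.0], [1.0, 0.0], [-0.8, 0.0]], [0.0, 0.0, 0.0],
                      ["E1", "E2", "E3"])
        corr = genetic_correlation_matrix(fit).to_numpy()
        assert np.allclose(np.abs(corr), 1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_zero_loadings_identity(self):
        fit = _fa2fit([[0.0, 0.0]] * 3, [0.3, 0.2, 0.1], ["E1", "E2", "E3"])
        corr = genetic_correlation_matrix(fit).to_numpy()
        assert np.allclose(corr, np.eye(3))

    def test_zero_variance_environment_reported_missing(self):
        fit = _fa2fit([[0.0, 0.0], [1.0, 0.0]], [0.0, 0.5], ["E1", "E2"])
        corr = genetic_correlation_matrix(fit)
        assert np.isnan(corr.loc["E1", "E2"])
        assert np.isnan(corr.loc["E1", "E1"])


@pytest.fixture(scope="module")
def structured_fit():
    """A 40 x 5 table with strong low-rank G x E plus its REML fit."""
    lam = np.array([[0.5, 0.0], [0.55, 0.1], [0.45, -0.1], [0.6, 0.05], [0.5, 0.0]])
    psi = np.full(5, 0.02)
    blues, ses = simulate_gxe_table(40, lam, psi, env_means=np.linspace(3, 7, 5),
                                    sigma2_g=0.0, se=0.1, seed=31)
    table = GxETable(blues, ses)
    return table, fit_stage2_fa2(table)


class TestFitFA2:
    def test_strong_common_factor_recovered(self, structured_fit):
        table, fit = structured_fit
        corr = genetic_correlation_matrix(fit).to_numpy()
        off = corr[np.triu_indices(5, k=1)]
        assert np.nanmin(off) > 0.7
        assert fit.converged

    def test_identifiability_constraint_and_invariance(self, structured_fit):
        """Lambda obeys the rotation constraint; G is start-invariant."""
        table, fit = structured_fit
        lam = fit.loadings.to_numpy()
        assert lam[0, 1] == pytest.approx(0.0, abs=1e-12)
        for r in range(lam.shape[1]):
            nz = np.nonzero(np.abs(lam[:, r]) > 1e-10)[0]
            if len(nz):
                assert lam[nz[0], r] > 0
        refit = fit_stage2_fa2(table, start_jitter=0.5, start_seed=99)
        # the identified quantity is the total genetic covariance (the
        # main-effect/constant-loading split sits on a flat ridge)
        C1 = fit.sigma2_g + fit.G_env.to_numpy()
        C2 = refit.sigma2_g + refit.G_env.to_numpy()
        assert np.allclose(C1, C2, atol=1e-3)

    def test_se_weights_enter_only_relatively_on_complete_tables(self, structured_fit):
        table, fit = structured_fit
        doubled = GxETable(table.blues, table.ses * 2.0)
        fit2 = fit_stage2_fa2(doubled)
        assert np.allclose(fit2.env_effects, fit.env_effects, atol=1e-5)
        assert fit2.mu == pytest.approx(fit.mu, abs=1e-5)

    def test_few_environments_fall_back_to_fa1(self, small_gxe_table, caplog):
        fit = fit_stage2_fa2(small_gxe_table)
        assert fit.n_factors == 1
        assert fit.loadings.shape == (3, 1)

    def test_nrm_failure_falls_back_to_identity(self, small_gxe_table, monkeypatch):
        calls = {"n": 0}
        real = s2.fit_reml

        def failing_first(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 1:
                raise ConvergenceError("forced failure")
            return real(*args, **kwargs)

        monkeypatch.setattr(s2, "fit_reml", failing_first)
        nrm = pd.DataFrame(np.eye(5), index=small_gxe_table.genotypes,
                           columns=small_gxe_table.genotypes)
        fit = fit_stage2_fa2(small_gxe_table, nrm=nrm)
        assert fit.nrm_fallback
        assert not fit.used_nrm
        assert fit.converged

    def test_breeding_values_track_true_genotype_effects(self):
        lam = np.array([[0.3, 0.0], [0.35, 0.1], [0.25, -0.1], [0.3, 0.05]])
        blues, ses = simulate_gxe_table(
            60, lam, np.full(4, 0.05), env_means=np.array([3.0, 4.0, 5.0, 6.0]),
            sigma2_g=0.15, se=0.1, seed=17)
        # reconstruct the generating genotype effects via the same stream
        rng = np.random.default_rng(17)
        g_true = rng.normal(0.0, np.sqrt(0.15), 60)
        fit = fit_stage2_fa2(GxETable(blues, ses))
        bv = fit.breeding_values["value"].to_numpy()
        assert np.corrcoef(bv, g_true)[0, 1] > 0.8

    def test_sigma2_g_recovery_across_replicates(self):
        """Mean bias of sigma2_g below 25% over 10 medium simulations."""
        lam = np.array([[0.3, 0.0], [0.2, 0.15], [0.25, -0.1], [0.3, 0.1],
                        [0.2, 0.0], [0.25, 0.1]])
        truth = 0.12
        est = []
        for seed in range(10):
            blues, ses = simulate_gxe_table(
                50, lam, np.full(6, 0.04), env_means=np.linspace(3, 7, 6),
                sigma2_g=truth, se=0.08, missing_rate=0.15, seed=100 + seed)
            fit = fit_stage2_fa2(GxETable(blues, ses))
            # the main effect and a constant loading direction are aliased:
            # compare the implied average genetic covariance instead
            G = fit.G_env.to_numpy()
            est.append(fit.sigma2_g + G.sum() / G.size)
        implied_truth = truth + (lam @ lam.T + np.diag(np.full(6, 0.04))).mean()
        assert np.mean(est) == pytest.approx(implied_truth, rel=0.25)
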