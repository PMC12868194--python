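import numpy as np
import pandas as pd
import pytest

from eratrend.errors import InvalidConfigError
from eratrend.kinship import build_nrm, count_sibships
from eratrend.synthetic_data import (
    SyntheticConfig,
    ecology_preset,
    pedigree_with_release_years,
    simulate_met,
    simulate_pedigree,
)


class TestPresets:
    @pytest.mark.parametrize(
        "name,n_geno,n_envs",
        [("irrigated_lowland", 36, 8), ("rainfed_lowland", 24, 6), ("rainfed_upland", 20, 4)],
    )
    def test_design_dimensions(self, name, n_geno, n_envs):
        cfg = ecology_preset(name)
        assert cfg.n_genotypes == n_geno
        assert cfg.n_envs == n_envs
        assert cfg.n_reps == 3
        assert cfg.release_span == (1986, 2020)
        assert min(cfg.env_means) > 2.0 and max(cfg.env_means) < 8.5

    def test_unknown_ecology_raises(self):
        with pytest.raises(InvalidConfigError):
            ecology_preset("greenhouse")

    @pytest.mark.parametrize(
        "name,expected", [("irrigated_lowland", 32), ("rainfed_lowland", 22),
                          ("rainfed_upland", 14)],
    )
    def test_preset_pedigrees_give_target_sibship_counts(self, name, expected):
        """Relatedness clusters among trial entries match the design intent."""
        cfg = ecology_preset(name, seed=3)
        ped = simulate_pedigree(cfg.n_founders, cfg.n_families, cfg.family_sizes, seed=3)
        entries = ped.terminal_ids()[: cfg.n_genotypes]
        assert len(entries) == cfg.n_genotypes
        nrm = build_nrm(ped).loc[entries, entries]
        assert count_sibships(nrm) == expected


class TestSimulatePedigree:
    def test_founders_only_nrm_identity(self):
        ped = simulate_pedigree(5, 0, (), seed=1)
        assert np.allclose(build_nrm(ped).to_numpy(), np.eye(5))

    def test_same_seed_identical(self):
        a = simulate_pedigree(10, 3, (2, 3, 1), seed=9)
        b = simulate_pedigree(10, 3, (2, 3, 1), seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_two_families_two_nonsingleton_components(self):
        ped = simulate_pedigree(4, 2, (3, 2), seed=2)
        nrm = build_nrm(ped)
        arr = nrm.to_numpy()
        # brute-force components of the off-diagonal support
        n = len(arr)
        comp = list(range(n))
        for i in range(n):
            for j in range(n):
                if i != j and arr[i, j] > 0:
                    old, new = comp[j], comp[i]
                    comp = [new if c == old else c for c in comp]
        sizes = pd.Series(comp).value_counts()
        assert (sizes > 1).sum() == 2

    def test_too_many_families_raises(self):
        with pytest.raises(InvalidConfigError):
            simulate_pedigree(4, 3, (1, 1, 1), seed=0)

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(8, 2, (2, 2), seed=5)
        seen = set()
        for row in ped.records.itertuples(index=False):
            for p in (row.parent1, row.parent2):
                assert p == "" or p in seen
            seen.add(row.genotype)


class TestSimulateMet:
    def test_determinism(self):
        cfg = ecology_preset("rainfed_upland", seed=11)
        ped = simulate_pedigree(cfg.n_founders, cfg.n_families, cfg.family_sizes, seed=11)
        p1, t1 = simulate_met(cfg, ped, seed=11)
        p2, t2 = simulate_met(cfg, ped, seed=11)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_series_equal(t1.genetic_values, t2.genetic_values)

    def test_noise_free_degenerate_case(self):
        """With all variances, trend and slopes zero, plots equal mu_env + gamma."""
        k = 3
        cfg = SyntheticConfig(
            n_genotypes=6, n_envs=k, env_means=(3.0, 4.0, 5.0),
            true_beta=0.0, true_gamma=1.0, sigma2_tau=0.0,
            loadings=np.zeros((k, 2)), psi=np.zeros(k),
            sigma2_rep=0.0, sigma2_block=0.0, sigma2_error=0.0,
            missing_rate=0.0, n_founders=6, n_families=0, family_sizes=(),
        )
        cfg.covariate_params.dtf_slope = 0.0
        cfg.covariate_params.height_slope = 0.0
        plots, truth = simulate_met(cfg, seed=4)
        for trial, mu in zip(cfg.trial_names(), cfg.env_means):
            vals = plots.loc[plots["trial"] == trial, "yield_t_ha"]
            assert np.allclose(vals, mu + 1.0, atol=1e-12)

    def test_wrong_loadings_shape_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_envs=4, loadings=np.zeros((3, 2)))

    def test_alpha_lattice_layout(self):
        """Within each (trial, rep): genotypes unique, blocks partition them."""
        cfg = ecology_preset("rainfed_lowland", seed=8)
        ped = simulate_pedigree(cfg.n_founders, cfg.n_families, cfg.family_sizes, seed=8)
        plots, _ = simulate_met(cfg, ped, seed=8)
        for (trial, rep), sub in plots.groupby(["trial", "rep"]):
            assert not sub["genotype"].duplicated().any()
            sizes = sub.groupby("block")["genotype"].count()
            assert (sizes <= cfg.block_size).all()
            # at most one ragged block
            assert (sizes < cfg.block_size).sum() <= 1

    def test_every_genotype_in_at_least_two_environments(self):
        cfg = ecology_preset("rainfed_lowland", seed=13)
        cfg.missing_rate = 0.7
        ped = simulate_pedigree(cfg.n_founders, cfg.n_families, cfg.family_sizes, seed=13)
        plots, _ = simulate_met(cfg, ped, seed=13)
        envs_per_geno = plots.groupby("genotype")["trial"].nunique()
        assert (envs_per_geno >= 2).all()

    def test_tau_variance_matches_config(self):
        """Monte-Carlo: sample variance of tau over 10,000 genotypes ~ sigma2_tau."""
        k = 2
        cfg = SyntheticConfig(
            n_genotypes=10_000, n_envs=k, env_means=(4.0, 5.0),
            sigma2_tau=0.08, loadings=np.zeros((k, 2)), psi=np.zeros(k),
            missing_rate=0.0, n_reps=2, n_founders=10_000, n_families=0,
            family_sizes=(), block_size=50,
        )
        ped = simulate_pedigree(10_000, 0, (), seed=21)
        _, truth = simulate_met(cfg, ped, seed=21)
        assert truth.tau.var() == pytest.approx(0.08, rel=0.05)

    def test_ge_covariance_matches_config(self):
        """Monte-Carlo: empirical covariance of ge vectors ~ Lambda Lambda' + Psi."""
        k = 4
        lam = np.array([[0.4, 0.0], [0.3, 0.2], [0.5, -0.2], [0.2, 0.3]])
        psi = np.array([0.05, 0.1, 0.02, 0.08])
        cfg = SyntheticConfig(
            n_genotypes=10_000, n_envs=k, env_means=(3.0, 4.0, 5.0, 6.0),
            loadings=lam, psi=psi, missing_rate=0.0, n_reps=2,
            n_founders=10_000, n_families=0, family_sizes=(), block_size=50,
        )
        ped = simulate_pedigree(10_000, 0, (), seed=22)
        _, truth = simulate_met(cfg, ped, seed=22)
        emp = np.cov(truth.ge.to_numpy().T)
        assert np.abs(emp - cfg.ge_covariance).max() < 0.05

    def test_environment_mean_structure(self):
        """Per-environment plot means converge to mu_env + mean genetic value."""
        k = 2
        cfg = SyntheticConfig(
            n_genotypes=10_000, n_envs=k, env_means=(4.0, 6.0),
            true_beta=0.012, sigma2_tau=0.08,
            loadings=np.full((k, 2), 0.2), psi=np.full(k, 0.05),
            sigma2_rep=0.0, sigma2_block=0.0,  # rep effects do not average
            missing_rate=0.0, n_reps=2, n_founders=10_000, n_families=0,  # out over genotypes
            family_sizes=(), block_size=50,
        )
        ped = simulate_pedigree(10_000, 0, (), seed=23)
        plots, truth = simulate_met(cfg, ped, seed=23)
        gbar = truth.genetic_values.mean()
        for trial, mu in zip(cfg.trial_names(), cfg.env_means):
            observed = plots.loc[plots["trial"] == trial, "yield_t_ha"].mean()
            assert observed == pytest.approx(mu + gbar, abs=0.02 * (mu + gbar))

    def test_release_years_propagate_to_pedigree(self):
        cfg = ecology_preset("rainfed_upland", seed=2)
        ped = simulate_pedigree(cfg.n_founders, cfg.n_families, cfg.family_sizes, seed=2)
        plots, truth = simulate_met(cfg, ped, seed=2)
        ped2 = pedigree_with_release_years(ped, truth)
        released = ped2.released()
        assert set(released["genotype"]) == set(truth.release_years.index)
        assert released["release_year"].between(1986, 2020).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(missing_rate=1.0)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_reps=1)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(release_span=(2020, 1986))
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(sigma2_error=-0.1)
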