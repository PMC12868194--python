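"""Synthetic multi-environment ERA-trial data with known ground truth.

No raw plot data from the source trials is public, so this module generates
datasets with the same statistical anatomy the analysis assumes: released
varieties spanning 1986-2020 with a linear genetic trend plus deviations,
low-rank (two-factor) genotype-by-environment covariance, alpha-lattice
error structure (replicates with incomplete blocks), partial
genotype-by-environment connectivity, and yield-correlated covariates
(days to flowering, plant height). Every draw is recorded in a
:class:`Truth` object so parameter-recovery tests can compare estimates to
the generating values.

Three ecology presets mirror the source study's designs: irrigated lowland
(36 varieties, 8 trials), rainfed lowland (24 varieties, 6 trials) and
rainfed upland (20 varieties, 4 trials), all alpha lattices with 3
replications and environment means matching the per-trial yield levels
reported for those ecologies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .kinship import Pedigree, UNKNOWN

PHENOTYPE_COLUMNS = [
    "trial", "site", "country", "year", "ecology",
    "genotype", "rep", "block", "yield_t_ha", "dtf_days", "height_cm",
]


@dataclass
class CovariateParams:
    """Genotype-level covariate distributions and their yield slopes.

    Slopes are in t/ha per unit (per day for flowering, per cm for height);
    covariate contributions are centered so they do not shift trial means.
    """

    dtf_mean: float = 95.0
    dtf_sd: float = 10.0
    dtf_plot_sd: float = 3.0
    dtf_slope: float = 0.01
    height_mean: float = 110.0
    height_sd: float = 15.0
    height_plot_sd: float = 5.0
    height_slope: float = 0.004


@dataclass
class SyntheticConfig:
    """Full parameterisation of one simulated ecology/MET dataset."""

    ecology: str = "custom"
    n_genotypes: int = 24
    release_span: tuple[int, int] = (1986, 2020)
    true_beta: float = 0.012          # genetic trend, t/ha per year
    true_gamma: float | None = None   # trend intercept; None -> centered trend
    sigma2_tau: float = 0.08          # deviation variance around the trend
    n_envs: int = 6
    env_means: tuple[float, ...] | None = None       # t/ha per environment
    env_labels: tuple[tuple[str, str, int], ...] | None = None  # (site, country, year)
    loadings: np.ndarray | None = None               # n_envs x 2, t/ha
    psi: np.ndarray | None = None                    # n_envs specific variances
    sigma2_rep: float = 0.05
    sigma2_block: float = 0.03
    sigma2_error: float = 0.45
    n_reps: int = 3
    block_size: int = 6
    missing_rate: float = 0.2
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    n_families: int = 2
    family_sizes: tuple[int, ...] = (2, 2)
    n_founders: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.env_means is None:
            self.env_means = tuple(np.linspace(2.5, 7.5, self.n_envs))
        if self.env_labels is None:
            self.env_labels = tuple(
                (f"SITE{j + 1}", "NA", 2021) for j in range(self.n_envs)
            )
        if self.loadings is None:
            self.loadings = default_loadings(self.n_envs)
        if self.psi is None:
            self.psi = default_psi(self.n_envs)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.validate()

    def validate(self):
        for name in ("sigma2_tau", "sigma2_rep", "sigma2_block", "sigma2_error"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.n_reps < 2:
            raise InvalidConfigError("n_reps must be >= 2")
        if self.release_span[0] >= self.release_span[1]:
            raise InvalidConfigError("release_span must satisfy first < last")
        if self.loadings.shape != (self.n_envs, 2):
            raise InvalidConfigError(
                f"loadings must be {self.n_envs} x 2, got {self.loadings.shape}"
            )
        if self.psi.shape != (self.n_envs,):
            raise InvalidConfigError("psi must have one entry per environment")
        if np.any(self.psi < 0):
            raise InvalidConfigError("psi entries must be >= 0")
        if len(self.env_means) != self.n_envs:
            raise InvalidConfigError("env_means length must equal n_envs")
        if len(self.env_labels) != self.n_envs:
            raise InvalidConfigError("env_labels length must equal n_envs")
        if self.block_size < 2:
            raise InvalidConfigError("block_size must be >= 2")

    @property
    def gamma(self) -> float:
        """Effective trend intercept: centered so mean genetic deviation ~ 0."""
        if self.true_gamma is not None:
            return self.true_gamma
        mid = 0.5 * (self.release_span[0] + self.release_span[1])
        return -self.true_beta * mid

    @property
    def ge_covariance(self) -> np.ndarray:
        """Environment-level G x E covariance Lambda Lambda' + Psi."""
        return self.loadings @ self.loadings.T + np.diag(self.psi)

    def trial_names(self) -> list[str]:
        return [f"{site}_{year}" for site, _, year in self.env_labels]


@dataclass
class Truth:
    """Ground truth of one simulated dataset (all random draws recorded)."""

    beta: float
    gamma: float
    genetic_values: pd.Series    # per-genotype deviation gamma + beta*a + tau
    tau: pd.Series
    release_years: pd.Series
    ge: pd.DataFrame             # genotype x trial G x E draws
    ge_covariance: pd.DataFrame  # trial x trial Lambda Lambda' + Psi
    env_means: pd.Series         # per trial, t/ha

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta,
            "gamma": self.gamma,
            "genetic_values": self.genetic_values.to_dict(),
            "tau": self.tau.to_dict(),
            "release_years": {k: int(v) for k, v in self.release_years.items()},
            "ge": {g: row.to_dict() for g, row in self.ge.iterrows()},
            "ge_covariance": {t: row.to_dict() for t, row in self.ge_covariance.iterrows()},
            "env_means": self.env_means.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_loadings(n_envs: int) -> np.ndarray:
    """Deterministic two-factor loading pattern, 0.15-0.55 t/ha in magnitude.

    Factor 1 loads positively everywhere (a common performance axis); factor 2
    alternates in sign (a crossover axis). First row's second loading is zero,
    matching the identifiability constraint the estimator reports under.
    """
    lam = np.zeros((n_envs, 2))
    for j in range(n_envs):
        lam[j, 0] = 0.25 + 0.15 * (j % 3)
        lam[j, 1] = 0.0 if j == 0 else (0.18 if j % 2 else -0.15)
    return lam


def default_psi(n_envs: int) -> np.ndarray:
    """Deterministic specific variances, 0.01-0.15 t^2/ha^2."""
    return 0.01 + 0.14 * (np.arange(n_envs) % 4) / 3.0


# --- ecology design presets -----------------------------------------------

_PRESET_TABLE = {
    # ecology: (n_genotypes, beta, sigma2_error, block_size,
    #           env (site, country, year, mean t/ha),
    #           pedigree (n_founders, n_families, family_sizes), dtf_slope)
    "irrigated_lowland": dict(
        n_genotypes=36, true_beta=0.007, sigma2_error=0.55, block_size=6,
        envs=[
            ("Kilissi", "Guinea", 2021, 2.766),
            ("MBe", "CotedIvoire", 2021, 3.598),
            ("Ndiaye", "Senegal", 2021, 6.526),
            ("Niono", "Mali", 2021, 8.271),
            ("ValleeDuKou", "BurkinaFaso", 2021, 3.571),
            ("Kilissi", "Guinea", 2022, 3.311),
            ("MBe", "CotedIvoire", 2022, 7.528),
            ("Niono", "Mali", 2022, 6.038),
        ],
        n_founders=34, n_families=2, family_sizes=(3, 3), dtf_slope=-0.002,
    ),
    "rainfed_lowland": dict(
        n_genotypes=24, true_beta=0.012, sigma2_error=0.45, block_size=6,
        envs=[
            ("Fanaye", "Senegal", 2021, 2.753),
            ("Seredou", "Guinea", 2021, 2.353),
            ("Sikasso", "Mali", 2021, 6.298),
            ("Ibadan", "Nigeria", 2022, 4.893),
            ("Seredou", "Guinea", 2022, 3.624),
            ("Sikasso", "Mali", 2022, 4.102),
        ],
        n_founders=24, n_families=2, family_sizes=(2, 2), dtf_slope=0.01,
    ),
    "rainfed_upland": dict(
        n_genotypes=20, true_beta=0.010, sigma2_error=0.35, block_size=5,
        envs=[
            ("Longolora", "Mali", 2021, 2.156),
            ("MBe", "CotedIvoire", 2021, 2.640),
            ("Ibadan", "Nigeria", 2022, 3.494),
            ("Mopti", "Mali", 2022, 5.552),
        ],
        n_founders=18, n_families=4, family_sizes=(3, 3, 2, 2), dtf_slope=0.01,
    ),
}

ECOLOGIES = tuple(_PRESET_TABLE)


def ecology_preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Study-design preset for one of the three rice ecologies.

    Variety counts (36/24/20), trial counts (8/6/4), release window
    (1986-2020), 3 replications and per-trial mean yield levels follow the
    source trial network; variance magnitudes are the package's documented
    emulation choices.
    """
    if name not in _PRESET_TABLE:
        raise InvalidConfigError(
            f"unknown ecology {name!r}; choose from {sorted(_PRESET_TABLE)}"
        )
    p = _PRESET_TABLE[name]
    envs = p["envs"]
    cov = CovariateParams(dtf_slope=p["dtf_slope"])
    return SyntheticConfig(
        ecology=name,
        n_genotypes=p["n_genotypes"],
        release_span=(1986, 2020),
        true_beta=p["true_beta"],
        sigma2_error=p["sigma2_error"],
        n_envs=len(envs),
        env_means=tuple(e[3] for e in envs),
        env_labels=tuple((e[0], e[1], e[2]) for e in envs),
        n_reps=3,
        block_size=p["block_size"],
        covariate_params=cov,
        n_founders=p["n_founders"],
        n_families=p["n_families"],
        family_sizes=p["family_sizes"],
        seed=seed,
    )


# --- pedigree simulation --------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_families: int = 0,
    family_sizes=(),
    seed: int = 0,
) -> Pedigree:
    """Founders plus full-sib families from disjoint founder pairs.

    Each family is a full-sib group whose two parents are distinct founders;
    founder pairs are disjoint across families, so families are unrelated to
    each other. Founders have unknown parents and precede all offspring.
    """
    if n_founders < 2 and n_families > 0:
        raise InvalidConfigError("need >= 2 founders to form a family")
    if isinstance(family_sizes, int):
        family_sizes = (family_sizes,) * n_families
    family_sizes = tuple(int(s) for s in family_sizes)
    if len(family_sizes) != n_families:
        raise InvalidConfigError("family_sizes must have one entry per family")
    if any(s < 1 for s in family_sizes):
        raise InvalidConfigError("family sizes must be >= 1")
    if n_families > n_founders // 2:
        raise InvalidConfigError(
            f"{n_families} families need {2 * n_families} founders, have {n_founders}"
        )
    rng = np.random.default_rng(seed)
    founders = [f"F{k + 1:03d}" for k in range(n_founders)]
    order = rng.permutation(n_founders)
    rows = [(f, UNKNOWN, UNKNOWN) for f in founders]
    for fam in range(n_families):
        p1, p2 = founders[order[2 * fam]], founders[order[2 * fam + 1]]
        for k in range(family_sizes[fam]):
            rows.append((f"G{fam + 1:02d}_{k + 1:02d}", p1, p2))
    df = pd.DataFrame(rows, columns=["genotype", "parent1", "parent2"])
    df["release_year"] = np.nan
    return Pedigree(df)


def pedigree_with_release_years(pedigree: Pedigree, truth: Truth) -> Pedigree:
    """Copy of the pedigree with the simulated release years filled in."""
    df = pedigree.records.copy()
    years = truth.release_years
    df["release_year"] = df["genotype"].map(years)
    return Pedigree(df)


# --- MET simulation -------------------------------------------------------

def _entries(config: SyntheticConfig, pedigree: Pedigree) -> list[str]:
    """Trial entries: terminal pedigree individuals (released varieties)."""
    terminals = pedigree.terminal_ids()
    if len(terminals) < config.n_genotypes:
        raise InvalidConfigError(
            f"pedigree has {len(terminals)} terminal individuals; "
            f"config needs {config.n_genotypes}"
        )
    return terminals[: config.n_genotypes]


def simulate_met(
    config: SyntheticConfig,
    pedigree: Pedigree | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, Truth]:
    """Simulate plot records for one ecology and return them with the truth.

    Plot yields follow

        y = mu_env + rep + block(rep) + g + ge + covariate terms + error

    with g = gamma + beta * release_year + tau (tau ~ N(0, sigma2_tau)) and
    per-genotype G x E vectors drawn from N(0, Lambda Lambda' + Psi).
    Missingness removes whole genotype-by-environment cells; every genotype
    is guaranteed to remain in at least two environments.
    """
    if pedigree is None:
        pedigree = simulate_pedigree(
            config.n_founders, config.n_families, config.family_sizes,
            seed=config.seed,
        )
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    genotypes = _entries(config, pedigree)
    m, k = len(genotypes), config.n_envs
    trials = config.trial_names()

    lo, hi = config.release_span
    years = rng.integers(lo, hi + 1, size=m)
    while len(np.unique(years)) < 2:
        years = rng.integers(lo, hi + 1, size=m)
    tau = rng.normal(0.0, np.sqrt(config.sigma2_tau), size=m)
    g_dev = config.gamma + config.true_beta * years + tau

    scores = rng.normal(size=(m, 2))
    ge = scores @ config.loadings.T
    ge = ge + rng.normal(size=(m, k)) * np.sqrt(config.psi)[None, :]

    cp = config.covariate_params
    dtf_g = rng.normal(cp.dtf_mean, cp.dtf_sd, size=m)
    hgt_g = rng.normal(cp.height_mean, cp.height_sd, size=m)

    # genotype x environment presence (whole cells absent)
    present = rng.random((m, k)) >= config.missing_rate
    for i in range(m):
        if present[i].sum() < 2:
            keep = rng.choice(k, size=2, replace=False)
            present[i] = False
            present[i, keep] = True
    for j in range(k):
        while present[:, j].sum() < 2:
            present[rng.integers(m), j] = True

    rep_eff = rng.normal(0.0, np.sqrt(config.sigma2_rep), size=(k, config.n_reps))

    rows = []
    for j, trial in enumerate(trials):
        site, country, year = config.env_labels[j]
        idx = np.where(present[:, j])[0]
        for r in range(config.n_reps):
            order = rng.permutation(idx)
            n_blocks = max(1, int(np.ceil(len(order) / config.block_size)))
            block_eff = rng.normal(0.0, np.sqrt(config.sigma2_block), size=n_blocks)
            for pos, i in enumerate(order):
                b = pos // config.block_size
                g = genotypes[i]
                dtf = dtf_g[i] + rng.normal(0.0, cp.dtf_plot_sd)
                hgt = hgt_g[i] + rng.normal(0.0, cp.height_plot_sd)
                y = (
                    config.env_means[j]
                    + rep_eff[j, r]
                    + block_eff[b]
                    + g_dev[i]
                    + ge[i, j]
                    + cp.dtf_slope * (dtf - cp.dtf_mean)
                    + cp.height_slope * (hgt - cp.height_mean)
                    + rng.normal(0.0, np.sqrt(config.sigma2_error))
                )
                rows.append(
                    (trial, site, country, year, config.ecology,
                     g, r + 1, b + 1, y, dtf, hgt)
                )
    plots = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)

    truth = Truth(
        beta=config.true_beta,
        gamma=config.gamma,
        genetic_values=pd.Series(g_dev, index=genotypes, name="genetic_value"),
        tau=pd.Series(tau, index=genotypes, name="tau"),
        release_years=pd.Series(years, index=genotypes, name="release_year"),
        ge=pd.DataFrame(ge, index=genotypes, columns=trials),
        ge_covariance=pd.DataFrame(config.ge_covariance, index=trials, columns=trials),
        env_means=pd.Series(list(config.env_means), index=trials, name="env_mean"),
    )
    return plots, truth


def simulate_gxe_table(
    n_genotypes: int,
    loadings: np.ndarray,
    psi: np.ndarray,
    env_means: np.ndarray,
    sigma2_g: float = 0.1,
    se: float = 0.15,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Directly simulate a genotype x environment BLUE table (stage-2 input).

    Cell value = env mean + g_i + ge_ij + N(0, se^2); all cells share the
    given standard error. Used for focused tests of the stage-2 estimator
    without running stage 1. Returns (blues, ses) DataFrames.
    """
    rng = np.random.default_rng(seed)
    loadings = np.asarray(loadings, dtype=float)
    psi = np.asarray(psi, dtype=float)
    k = loadings.shape[0]
    genos = [f"G{i + 1:03d}" for i in range(n_genotypes)]
    trials = [f"ENV{j + 1}_2021" for j in range(k)]
    g = rng.normal(0.0, np.sqrt(sigma2_g), size=n_genotypes)
    ge = rng.normal(size=(n_genotypes, 2)) @ loadings.T
    ge = ge + rng.normal(size=(n_genotypes, k)) * np.sqrt(psi)[None, :]
    y = np.asarray(env_means)[None, :] + g[:, None] + ge + rng.normal(0, se, (n_genotypes, k))
    if missing_rate > 0:
        drop = rng.random((n_genotypes, k)) < missing_rate
        for i in range(n_genotypes):
            if (~drop[i]).sum() < 2:
                drop[i] = True
                drop[i, rng.choice(k, 2, replace=False)] = False
        y = np.where(drop, np.nan, y)
    blues = pd.DataFrame(y, index=genos, columns=trials)
    ses = pd.DataFrame(np.where(np.isnan(y), np.nan, se), index=genos, columns=trials)
    return blues, ses
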