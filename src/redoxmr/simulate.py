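"""Seeded synthetic surgical-cohort generator.

The generator encodes the causal structure the downstream analysis assumes,
so every stage can be exercised without any external data:

* plasma Lp(a) is lognormal and almost entirely genetically determined
  (additive effects of seven LPA-region variants on log-Lp(a), with a
  configurable genetic variance fraction defaulting to 0.90);
* diabetics run lower Lp(a) (a negative shift on the log scale);
* the eNOS-derived component of arterial superoxide rises with Lp(a) in
  nondiabetics only, so the L-NAME delta (post-inhibition minus basal
  chemiluminescence) is positively associated with Lp(a) in nondiabetics and
  flat in diabetics, and the BH4/BH2 ratio falls with Lp(a);
* NADPH-stimulated (NOX-derived) superoxide is independent of Lp(a);
* cardiovascular death follows an exponential proportional-hazards model
  whose Lp(a) effect acts purely through log basal superoxide by default
  (beta_lpa_direct = 0 encodes full mediation).

Linkage disequilibrium between the variants comes from a Gaussian copula:
each of a subject's two haploid draws is a multivariate normal vector cut at
the allele-frequency quantile per locus, so a single latent correlation
matrix tunes pairwise r-squared without a haplotype reference panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from ._errors import ConfigurationError, DataError
from .genetics import GenotypeMatrix, write_genotypes

__all__ = [
    "VariantSpec",
    "RedoxParams",
    "Bh4Params",
    "SurvivalParams",
    "SimulationConfig",
    "PHENOTYPE_COLUMNS",
    "default_variants",
    "simulate_genotypes",
    "simulate_exposures",
    "simulate_survival",
    "simulate_cohort",
    "generate_cohort",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class VariantSpec:
    """One instrument variant: alt-allele frequency and its additive effect
    on log-Lp(a) (per alternative allele, log mg/dL scale)."""

    rsid: str
    alt_freq: float
    beta_lpa: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alt_freq <= 0.5:
            raise ConfigurationError(
                f"{self.rsid}: alt_freq must lie in (0, 0.5], got {self.alt_freq}"
            )


def default_variants() -> list[VariantSpec]:
    """The seven LPA-region instruments with plausible rare-ish frequencies
    and per-allele effects sized so the alternative-score group runs a few
    fold above the reference group's Lp(a)."""
    return [
        VariantSpec("rs10455872", 0.07, 0.50),
        VariantSpec("rs3798220", 0.02, 0.55),
        VariantSpec("rs186696265", 0.02, 0.60),
        VariantSpec("rs76735376", 0.03, 0.40),
        VariantSpec("rs1800589", 0.15, 0.25),
        VariantSpec("rs140570886", 0.02, 0.55),
        VariantSpec("rs1801693", 0.12, 0.20),
    ]


@dataclass
class RedoxParams:
    """Vascular superoxide generator.  Units: log RLU; slopes per mg/dL Lp(a)."""

    nox_mean: float = 2.2
    nox_sd: float = 0.35
    enos_base: float = 1.0
    theta_lpa_enos: float = 0.01
    theta_lpa_enos_diabetic: float = 0.0
    noise_sd: float = 0.28
    lname_base: float = -0.2
    lname_noise_sd: float = 0.1
    vas_inhib: float = 0.7
    vas_noise_sd: float = 0.2


@dataclass
class Bh4Params:
    base_ratio: float = 1.6
    slope_vs_lpa: float = -0.004  # per mg/dL, on log ratio
    noise_sd: float = 0.3
    bh2_log_mean: float = 1.1
    bh2_log_sd: float = 0.3


@dataclass
class SurvivalParams:
    baseline_rate: float = 4.0e-4  # events / year at log basal O2 = 0
    beta_o2: float = 2.0  # log-hazard per log-RLU basal superoxide
    beta_lpa_direct: float = 0.0  # 0 encodes full mediation
    censor_rate: float = 0.1367  # median censoring ~5.07 years
    max_followup_years: float = 10.0
    covariate_betas: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_subjects: int = 1027
    variants: list[VariantSpec] = field(default_factory=default_variants)
    latent_corr: np.ndarray | float | None = 0.75  # scalar -> equicorrelation
    lpa_log_median: float = 2.3  # reference-group log-median (~10 mg/dL)
    genetic_var_fraction: float | None = 0.9
    lpa_noise_sd: float | None = None  # used when genetic_var_fraction is None
    lpa_diabetes_shift: float = -0.25  # log scale; diabetics run lower Lp(a)
    diabetes_prev: float = 0.209
    apob_params: tuple[float, float] = (4.50, 0.25)  # log mg/dL
    hscrp_params: tuple[float, float] = (0.70, 0.90)  # log mg/L
    mda_params: tuple[float, float] = (0.40, 0.40)  # log umol/L
    redox_params: RedoxParams = field(default_factory=RedoxParams)
    bh4_params: Bh4Params = field(default_factory=Bh4Params)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 <= self.diabetes_prev <= 1.0:
            raise ConfigurationError("diabetes_prev must lie in [0, 1]")
        if self.genetic_var_fraction is not None and not (
            0.0 <= self.genetic_var_fraction <= 1.0
        ):
            raise ConfigurationError("genetic_var_fraction must lie in [0, 1]")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ConfigurationError("variant rsids must be unique")
        sp = self.survival_params
        if min(sp.baseline_rate, sp.censor_rate, sp.max_followup_years) < 0:
            raise ConfigurationError("survival rates and follow-up must be nonnegative")

    def corr_matrix(self) -> np.ndarray:
        k = len(self.variants)
        lc = self.latent_corr
        if lc is None:
            lc = 0.0
        if np.isscalar(lc):
            rho = float(lc)
            C = np.full((k, k), rho)
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(lc, dtype=float)
        if C.shape != (k, k):
            raise ConfigurationError(f"latent_corr must be {k}x{k}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ConfigurationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ConfigurationError("latent_corr must have a unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigurationError("latent_corr must be positive semidefinite")
        return C


#: canonical column order of the phenotype table
PHENOTYPE_COLUMNS = [
    "subject_id", "age", "sex", "diabetes", "hypertension", "smoking",
    "family_history", "prior_mi", "urgent_surgery", "bmi", "lpa", "apob",
    "hscrp", "mda", "bh4", "bh2", "basal_o2", "post_lname_o2", "nadph_o2",
    "post_vas2870_o2", "followup_years", "cv_death",
]

_STAGES = ("genotypes", "exposures", "survival")


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Stable per-stage child generator from the single config seed."""
    idx = _STAGES.index(stage)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(idx,))
    )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw {0,1,2} dosages for the instrument variants under the Gaussian
    copula LD model (two latent haploid draws per subject)."""
    C = config.corr_matrix()
    rng = _rng_for(config, "genotypes")
    k = len(config.variants)
    n = config.n_subjects
    # small jitter keeps Cholesky defined for exactly singular PSD matrices
    L = np.linalg.cholesky(C + 1e-10 * np.eye(k))
    thresholds = sps.norm.ppf(
        [1.0 - v.alt_freq for v in config.variants]
    )  # latent above threshold -> alternative allele
    z = rng.standard_normal((2 * n, k)) @ L.T
    alleles = (z > thresholds).astype(np.int16)
    dosage = alleles[:n] + alleles[n:]
    subjects = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(subjects, [v.rsid for v in config.variants], dosage)


def _resolve_noise_sd(config: SimulationConfig, glin: np.ndarray) -> float:
    f = config.genetic_var_fraction
    if f is None:
        if config.lpa_noise_sd is None:
            raise ConfigurationError("set genetic_var_fraction or lpa_noise_sd")
        return float(config.lpa_noise_sd)
    vg = float(np.var(glin))
    if f == 0.0:
        if vg > 0:
            raise ConfigurationError(
                "genetic_var_fraction=0 unattainable with nonzero variant effects; "
                "set the betas to zero or give lpa_noise_sd directly"
            )
        if config.lpa_noise_sd is None:
            raise ConfigurationError("with genetic_var_fraction=0 give lpa_noise_sd")
        return float(config.lpa_noise_sd)
    if vg == 0.0:
        raise ConfigurationError(
            f"genetic_var_fraction={f} unattainable: realized genetic variance of "
            "log-Lp(a) is 0 (all betas zero or variants monomorphic in this draw)"
        )
    if f == 1.0:
        return 0.0
    return math.sqrt(vg * (1.0 - f) / f)


def simulate_exposures(gm: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Phenotypes, redox panel and biopterins for simulated genotypes; the
    survival columns are left empty (NaN)."""
    rng = _rng_for(config, "exposures")
    n = gm.n_subjects
    betas = np.array([v.beta_lpa for v in config.variants])
    if gm.rsids != [v.rsid for v in config.variants]:
        raise DataError("genotype matrix variants do not match the configuration")
    glin = gm.dosage.astype(float) @ betas

    diabetes = (rng.random(n) < config.diabetes_prev).astype(int)
    noise_sd = _resolve_noise_sd(config, glin)
    log_lpa = (
        config.lpa_log_median
        + glin
        + config.lpa_diabetes_shift * diabetes
        + rng.normal(0.0, noise_sd, n)
    )
    lpa = np.exp(log_lpa)

    # covariates independent of genotype by construction (MR independence)
    age = np.clip(rng.normal(67.0, 9.0, n), 40.0, 92.0)
    sex = (rng.random(n) < 0.82).astype(int)
    hypertension = (rng.random(n) < 0.72).astype(int)
    smoking = (rng.random(n) < 0.55).astype(int)
    family_history = (rng.random(n) < 0.40).astype(int)
    prior_mi = (rng.random(n) < 0.30).astype(int)
    urgent_surgery = (rng.random(n) < 0.15).astype(int)
    bmi = np.clip(rng.normal(28.6, 4.3, n), 17.0, 50.0)

    rp = config.redox_params
    theta = np.where(diabetes == 1, rp.theta_lpa_enos_diabetic, rp.theta_lpa_enos)
    log_basal = rp.enos_base + theta * lpa + rng.normal(0.0, rp.noise_sd, n)
    basal = np.exp(log_basal)
    # L-NAME arm: multiplicative response keeps readouts positive; the delta
    # (post - basal) rises with Lp(a) through theta and is negative at low
    # Lp(a) (recoupled eNOS)
    d = rp.lname_base + theta * lpa + rng.normal(0.0, rp.lname_noise_sd, n)
    post_lname = basal * np.exp(d)
    nadph = np.exp(rp.nox_mean + rng.normal(0.0, rp.nox_sd, n))
    post_vas = nadph * np.exp(-(rp.vas_inhib + rng.normal(0.0, rp.vas_noise_sd, n)))

    bp = config.bh4_params
    bh2 = np.exp(bp.bh2_log_mean + rng.normal(0.0, bp.bh2_log_sd, n))
    ratio = bp.base_ratio * np.exp(bp.slope_vs_lpa * lpa + rng.normal(0.0, bp.noise_sd, n))
    bh4 = ratio * bh2

    apob = np.exp(rng.normal(*config.apob_params, n))
    hscrp = np.exp(rng.normal(*config.hscrp_params, n))
    mda = np.exp(rng.normal(*config.mda_params, n))

    df = pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "age": age,
            "sex": sex,
            "diabetes": diabetes,
            "hypertension": hypertension,
            "smoking": smoking,
            "family_history": family_history,
            "prior_mi": prior_mi,
            "urgent_surgery": urgent_surgery,
            "bmi": bmi,
            "lpa": lpa,
            "apob": apob,
            "hscrp": hscrp,
            "mda": mda,
            "bh4": bh4,
            "bh2": bh2,
            "basal_o2": basal,
            "post_lname_o2": post_lname,
            "nadph_o2": nadph,
            "post_vas2870_o2": post_vas,
            "followup_years": np.nan,
            "cv_death": np.nan,
        }
    )
    return df[PHENOTYPE_COLUMNS]


def simulate_survival(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Fill the survival columns: exponential event times under a
    proportional-hazards model on log basal superoxide (and, optionally, a
    direct Lp(a) path and covariate effects), with independent exponential
    censoring truncated at the administrative follow-up limit."""
    sp = config.survival_params
    if min(sp.baseline_rate, sp.censor_rate, sp.max_followup_years) < 0:
        raise ConfigurationError("negative rate in survival configuration")
    for col in ("basal_o2", "lpa"):
        if cohort[col].isna().any() or (cohort[col] <= 0).any():
            raise DataError(f"survival simulation needs positive {col} for all subjects")
    rng = _rng_for(config, "survival")
    n = len(cohort)
    eta = sp.beta_o2 * np.log(cohort["basal_o2"].to_numpy()) + sp.beta_lpa_direct * np.log(
        cohort["lpa"].to_numpy()
    )
    for name, b in sp.covariate_betas.items():
        eta = eta + b * cohort[name].to_numpy(dtype=float)
    lam = sp.baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0, n) / np.maximum(lam, 1e-300)
    if sp.censor_rate > 0:
        t_cens = rng.exponential(1.0 / sp.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, sp.max_followup_years)
    followup = np.minimum(t_event, t_cens)
    death = (t_event <= t_cens) & (followup > 0)

    out = cohort.copy()
    out["followup_years"] = followup
    out["cv_death"] = death.astype(int)
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes plus a fully populated phenotype/survival table."""
    gm = simulate_genotypes(config)
    pheno = simulate_exposures(gm, config)
    pheno = simulate_survival(pheno, config)
    return gm, pheno


# ---------------------------------------------------------------------------
# configuration (de)serialization and on-disk cohorts
# ---------------------------------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    d = {
        "n_subjects": config.n_subjects,
        "variants": [asdict(v) for v in config.variants],
        "latent_corr": (
            config.latent_corr
            if config.latent_corr is None or np.isscalar(config.latent_corr)
            else np.asarray(config.latent_corr).tolist()
        ),
        "lpa_log_median": config.lpa_log_median,
        "genetic_var_fraction": config.genetic_var_fraction,
        "lpa_noise_sd": config.lpa_noise_sd,
        "lpa_diabetes_shift": config.lpa_diabetes_shift,
        "diabetes_prev": config.diabetes_prev,
        "apob_params": list(config.apob_params),
        "hscrp_params": list(config.hscrp_params),
        "mda_params": list(config.mda_params),
        "redox_params": asdict(config.redox_params),
        "bh4_params": asdict(config.bh4_params),
        "survival_params": asdict(config.survival_params),
        "seed": config.seed,
    }
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "variants" in d:
        d["variants"] = [VariantSpec(**v) for v in d["variants"]]
    for key, cls in (("redox_params", RedoxParams), ("bh4_params", Bh4Params),
                     ("survival_params", SurvivalParams)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    for key in ("apob_params", "hscrp_params", "mda_params"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def generate_cohort(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Simulate and write the cohort: VCF + dosage TSV genotypes, a phenotype
    TSV, and a YAML echo of the configuration.  Returns the file paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    gm, pheno = simulate_cohort(config)
    paths = {
        "vcf": out / "genotypes.vcf",
        "dosage_tsv": out / "genotypes_dosage.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "config": out / "config.yaml",
    }
    try:
        write_genotypes(gm, paths["vcf"], "vcf")
        write_genotypes(gm, paths["dosage_tsv"], "tsv")
        pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
        save_config(config, paths["config"])
    except OSError as exc:
        raise DataError(f"failed writing cohort under {out}: {exc}") from exc
    return paths
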