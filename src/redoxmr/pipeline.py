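"""Pipeline orchestration: simulate -> genetics -> redox -> inference ->
causal, with cached stage outputs under a single directory and a
machine-readable report.

Every stage reads its inputs from the output directory (or from
user-supplied genotype/phenotype files), writes its own TSV artifacts, and
contributes a block to ``report.json``.  All numeric results are
reproducible from the configuration and seed alone: the single seed fans out
to per-stage child seeds, and the report carries no timestamps.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigurationError, DataError, FitError
from . import causal, genetics, inference, redox, simulate

__all__ = ["STAGES", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("redoxmr")

STAGES = ["simulate", "assoc", "grs", "ld", "redox", "mr", "survive", "mediate", "power"]

#: covariate set for the adjusted survival models
SURVIVAL_COVARIATES = [
    "age", "sex", "hypertension", "smoking", "bmi", "diabetes",
    "family_history", "prior_mi", "urgent_surgery", "apob",
]

_SURVIVAL_COLUMNS = {"followup_years", "cv_death"}


def load_pipeline_config(path) -> dict:
    """A pipeline config YAML: a ``simulation`` block (SimulationConfig
    fields) plus optional ``genotypes``/``phenotypes`` paths for user data
    and analysis options."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: pipeline config must be a mapping")
    return raw


def _analysis_seed(sim_config: simulate.SimulationConfig, label: str) -> np.random.SeedSequence:
    offset = {"mr": 11, "boot": 12}[label]
    return np.random.SeedSequence(entropy=int(sim_config.seed), spawn_key=(offset,))


class _Pipeline:
    def __init__(self, out_dir: Path, sim_config: simulate.SimulationConfig,
                 genotype_path: Path | None = None, phenotype_path: Path | None = None):
        self.out = out_dir
        self.config = sim_config
        self.genotype_path = genotype_path
        self.phenotype_path = phenotype_path
        self.report: dict = {}
        self.warnings: list[str] = []

    # -- cached inputs ----------------------------------------------------
    def genotypes(self) -> genetics.GenotypeMatrix:
        path = self.genotype_path or self.out / "genotypes_dosage.tsv"
        if not Path(path).exists():
            raise DataError(f"genotypes not found at {path}; run the simulate stage "
                            "or pass a genotype file")
        return genetics.read_genotypes(path)

    def phenotypes(self) -> pd.DataFrame:
        path = self.phenotype_path or self.out / "phenotypes.tsv"
        if not Path(path).exists():
            raise DataError(f"phenotypes not found at {path}; run the simulate stage "
                            "or pass a phenotype file")
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
        required = set(simulate.PHENOTYPE_COLUMNS) - _SURVIVAL_COLUMNS - {"subject_id"}
        missing = sorted(required - set(df.columns))
        if missing:
            raise DataError("phenotype table lacks required columns: " + ", ".join(missing))
        return df

    def grs(self) -> genetics.GrsResult:
        gm = self.genotypes()
        return genetics.build_grs(gm, gm.rsids)

    def has_survival(self, df: pd.DataFrame) -> bool:
        return _SURVIVAL_COLUMNS <= set(df.columns) and df["cv_death"].notna().any()

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        paths = simulate.generate_cohort(self.config, self.out)
        self.report["simulate"] = {
            "n_subjects": self.config.n_subjects,
            "files": {k: p.name for k, p in paths.items()},
        }

    def stage_assoc(self) -> None:
        gm = self.genotypes()
        pheno = self.phenotypes()
        results, selected = genetics.snp_association(gm, pheno["lpa"].to_numpy())
        rows = [r.to_dict() | {"selected": r.rsid in selected} for r in results]
        df = pd.DataFrame(rows)
        df.to_csv(self.out / "association.tsv", sep="\t", index=False)
        self.report["association"] = {"table": rows, "selected": selected}

    def stage_grs(self) -> None:
        res = self.grs()
        res.to_frame().to_csv(self.out / "grs.tsv", sep="\t", index=False)
        self.report["grs"] = {"group_sizes": res.group_sizes,
                              "instruments": res.instrument_rsids}

    def stage_ld(self) -> None:
        gm = self.genotypes()
        dp, r2, pairs = genetics.ld_matrices(gm)
        # D' upper triangle, r^2 lower, per the conventional combined display
        combined = dp.where(np.triu(np.ones_like(dp, dtype=bool), 1),
                            r2).where(~np.eye(len(dp), dtype=bool), 1.0)
        dp.to_csv(self.out / "ld_dprime.tsv", sep="\t")
        r2.to_csv(self.out / "ld_r2.tsv", sep="\t")
        combined.to_csv(self.out / "ld_combined.tsv", sep="\t")
        self.report["ld"] = {
            "dprime": dp.to_numpy().tolist(),
            "r2": r2.to_numpy().tolist(),
            "rsids": list(dp.columns),
            "median_offdiag_dprime": float(np.median(dp.to_numpy()[np.triu_indices(len(dp), 1)])),
        }

    def stage_redox(self) -> None:
        pheno = self.phenotypes()
        derived = redox.derive_redox_indices(pheno)
        derived.to_csv(self.out / "phenotypes_derived.tsv", sep="\t", index=False)
        grs = self.grs()
        alt = grs.group == "alternative"
        ref = grs.group == "reference"
        nondiab = pheno["diabetes"].to_numpy() == 0
        tert = redox.tertile_groups(pheno["lpa"].to_numpy())
        hi = tert == "medhigh"

        def contrast(values, a, b):
            return {
                "mean_a": float(np.mean(values[a])), "mean_b": float(np.mean(values[b])),
                "test": inference.two_group_test(values[a], values[b]).to_dict(),
            }

        basal = derived["basal_o2"].to_numpy()
        delta = derived["lname_delta_derived"].to_numpy()
        nadph = derived["nadph_o2"].to_numpy()
        ratio = derived["bh_ratio_derived"].to_numpy()
        lpa = pheno["lpa"].to_numpy()
        self.report["redox"] = {
            "grs_basal": contrast(basal, alt, ref),
            "grs_lpa": contrast(lpa, alt, ref),
            "grs_lname_delta": contrast(delta, alt, ref),
            "grs_nadph": contrast(nadph, alt, ref),
            "lpa_tertile_basal": contrast(basal, hi, ~hi),
            "lpa_tertile_basal_nondiabetic": contrast(
                basal[nondiab], hi[nondiab], ~hi[nondiab]),
            "lpa_tertile_bh_ratio": contrast(ratio, hi, ~hi),
            "diabetes_lpa": contrast(lpa, pheno["diabetes"].to_numpy() == 1,
                                     pheno["diabetes"].to_numpy() == 0),
        }
        # moderation of the Lp(a) -> basal superoxide slope by diabetes
        seed = _analysis_seed(self.config, "boot").generate_state(1)[0] % (2**31)
        mod = inference.moderation(
            np.log(basal), lpa, pheno["diabetes"].to_numpy(), seed=int(seed))
        self.report["moderation"] = mod.to_dict()

    def stage_mr(self) -> None:
        pheno = self.phenotypes()
        gm = self.genotypes()
        grs = self.grs()
        lpa = pheno["lpa"].to_numpy()
        log_basal = np.log(pheno["basal_o2"].to_numpy())
        nondiab = pheno["diabetes"].to_numpy() == 0
        confounders = pheno[SURVIVAL_COVARIATES]
        check = causal.validate_instrument(grs, lpa, confounders,
                                           genotypes=gm, outcome=log_basal)
        if not check.relevance_pass:
            self.warnings.append("weak instrument: first-stage F <= 10")
        seed = int(_analysis_seed(self.config, "mr").generate_state(1)[0] % (2**31))
        est = causal.mr_estimate(grs, lpa, log_basal, method="two_stage",
                                 seed=seed, subset=nondiab)
        est_all = causal.mr_estimate(grs, lpa, log_basal, method="grs_contrast",
                                     seed=seed + 1)
        bx, sx, by, sy, rsids = causal.per_variant_associations(gm, lpa, log_basal)
        egger = causal.mr_egger(bx, sx, by, sy)
        self.report["mr"] = {
            "instrument_check": check.to_dict(),
            "two_stage_nondiabetic": est.to_dict(),
            "grs_contrast_all": est_all.to_dict(),
            "egger": egger.to_dict(),
            "egger_variants": rsids,
        }

    def _survival_frame(self) -> tuple[pd.DataFrame, genetics.GrsResult] | None:
        pheno = self.phenotypes()
        if not self.has_survival(pheno):
            self.warnings.append(
                "phenotypes lack usable survival columns (followup_years, cv_death); "
                "survival/mediation stages skipped")
            log.warning(self.warnings[-1])
            return None
        return pheno, self.grs()

    def stage_survive(self) -> None:
        sf = self._survival_frame()
        if sf is None:
            self.report["survival"] = {"skipped": True}
            return
        pheno, grs = sf
        keep = np.isin(grs.group, ["reference", "alternative"])
        expo = (grs.group == "alternative").astype(float)
        block = {}
        for label, adjust in (("unadjusted", False), ("adjusted", True)):
            cols = [expo[keep]]
            names = ["grs_alternative"]
            if adjust:
                for c in SURVIVAL_COVARIATES:
                    cols.append(pheno.loc[keep, c].to_numpy(dtype=float))
                    names.append(c)
            try:
                fit = inference.cox_fit(
                    pheno.loc[keep, "followup_years"].to_numpy(),
                    pheno.loc[keep, "cv_death"].to_numpy(),
                    np.column_stack(cols), names=names)
                hr, ci, p = fit.triple("grs_alternative")
                block[label] = {"hr": hr, "ci": list(ci), "p": p,
                                "n": fit.n, "n_events": fit.n_events}
            except FitError as exc:
                block[label] = {"error": str(exc)}
        # continuous per-SD score among >1-variant carriers
        cont = grs.continuous_score
        ck = np.isfinite(cont)
        if ck.sum() >= 10 and pheno.loc[ck, "cv_death"].sum() >= 1:
            try:
                fitc = inference.cox_fit(
                    pheno.loc[ck, "followup_years"].to_numpy(),
                    pheno.loc[ck, "cv_death"].to_numpy(),
                    cont[ck][:, None], names=["grs_per_sd"])
                hr, ci, p = fitc.triple("grs_per_sd")
                block["continuous_per_sd"] = {"hr": hr, "ci": list(ci), "p": p,
                                              "n": fitc.n, "n_events": fitc.n_events}
            except FitError as exc:
                block["continuous_per_sd"] = {"error": str(exc)}
        self.report["survival"] = block

    def stage_mediate(self) -> None:
        sf = self._survival_frame()
        if sf is None:
            self.report["mediation"] = {"skipped": True}
            return
        pheno, grs = sf
        keep = np.isin(grs.group, ["reference", "alternative"])
        expo = (grs.group == "alternative").astype(float)
        med = np.log(pheno["basal_o2"].to_numpy())
        res = causal.mediation_cox(
            pheno.loc[keep, "followup_years"].to_numpy(),
            pheno.loc[keep, "cv_death"].to_numpy(),
            expo[keep], med[keep],
            covariates=pheno.loc[keep, SURVIVAL_COVARIATES])
        self.report["mediation"] = {"grs_group": res.to_dict()}
        # plasma Lp(a) tertile contrast, mirrored on the phenotype side
        tert = redox.tertile_groups(pheno["lpa"].to_numpy())
        hi = (tert == "medhigh").astype(float)
        res2 = causal.mediation_cox(
            pheno["followup_years"].to_numpy(), pheno["cv_death"].to_numpy(),
            hi, med, covariates=pheno[SURVIVAL_COVARIATES])
        self.report["mediation"]["lpa_medhigh"] = res2.to_dict()

    def stage_power(self) -> None:
        # the study's design calculation: delta in log basal superoxide with a
        # 1:2 allocation (bottom tertile vs upper two) of 100 subjects
        spec = inference.power_two_sample(delta=0.67, sd=0.28, n1=33, n2=67, alpha=0.05)
        self.report["power"] = spec.to_dict()


def run_pipeline(
    config_path=None,
    out_dir="pipeline_out",
    stages: list[str] | None = None,
    seed: int | None = None,
    sim_config: simulate.SimulationConfig | None = None,
    genotypes=None,
    phenotypes=None,
) -> dict:
    """Run the requested stages (default: all) and write ``report.json``.

    Identical configuration and seed produce a byte-identical report.  When
    ``genotypes``/``phenotypes`` paths are given the simulate stage is
    skipped and user files are analyzed instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw: dict = {}
    if config_path is not None:
        raw = load_pipeline_config(config_path)
    if sim_config is None:
        sim_config = simulate.config_from_dict(raw.get("simulation", {}))
    if seed is not None:
        sim_config.seed = int(seed)
    genotypes = genotypes or raw.get("genotypes")
    phenotypes = phenotypes or raw.get("phenotypes")

    requested = list(stages) if stages else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ConfigurationError("unknown stages: " + ", ".join(unknown))
    if genotypes or phenotypes:
        requested = [s for s in requested if s != "simulate"]
    requested = [s for s in STAGES if s in requested]  # canonical order

    pipe = _Pipeline(out, sim_config,
                     Path(genotypes) if genotypes else None,
                     Path(phenotypes) if phenotypes else None)
    for stage in requested:
        log.info("running stage %s", stage)
        getattr(pipe, f"stage_{stage}")()

    report = {
        "software": {"name": "redoxmr", "version": __version__},
        "seed": sim_config.seed,
        "config": simulate.config_to_dict(sim_config),
        "stages_run": requested,
        "warnings": pipe.warnings,
        "results": pipe.report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    _write_summary(report, out / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    """Human-readable digest; numbers displayed at 3 dp like printed HRs."""
    lines = [f"redoxmr {report['software']['version']}  seed={report['seed']}"]
    res = report["results"]
    if "grs" in res:
        lines.append("GRS groups: " + ", ".join(
            f"{k}={v}" for k, v in res["grs"]["group_sizes"].items()))
    if "mr" in res:
        ic = res["mr"]["instrument_check"]
        lines.append(f"first-stage F = {ic['f_statistic']:.3f} "
                     f"(relevance {'pass' if ic['relevance_pass'] else 'FAIL'})")
        ts = res["mr"]["two_stage_nondiabetic"]
        lines.append(f"two-stage MR (nondiabetics): {ts['estimate']:.5f} log-RLU per mg/dL")
        lines.append(f"Egger intercept p = {res['mr']['egger']['intercept_p']:.3f}")
    if "survival" in res and "unadjusted" in res.get("survival", {}):
        for lab in ("unadjusted", "adjusted", "continuous_per_sd"):
            blk = res["survival"].get(lab)
            if blk and "hr" in blk:
                lines.append(
                    f"Cox {lab}: HR {blk['hr']:.3f} "
                    f"[{blk['ci'][0]:.3f}-{blk['ci'][1]:.3f}], p={blk['p']:.3f}")
    if "mediation" in res and "grs_group" in res.get("mediation", {}):
        m = res["mediation"]["grs_group"]
        lines.append(
            f"mediation: unadjusted HR {m['unadjusted']['hr']:.3f} -> "
            f"adjusted {m['mediator_adjusted']['hr']:.3f} "
            f"(attenuation {m['attenuation_pct']:.1f}%)")
    path.write_text("\n".join(lines) + "\n")
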